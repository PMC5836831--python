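"""Access to the packaged marker tables, named inserts, and seed template.

The seven TSV tables transcribe the published candidate-marker tables row by
row (gene, dbSNP id, 10-nt flanks, ancestral/minor alleles, K_D of both
alleles in nM, direction, Z, significance bin, rank, free-text annotation).
Typographic ambiguities of the source layout are flagged per row in the
``flags`` column rather than silently resolved.
"""

from __future__ import annotations

import functools
from importlib import resources
from pathlib import Path

import yaml

from .records import MarkerRecord
from .sequence_io import parse_marker_table

TABLE_NUMBERS = tuple(range(1, 8))


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("tbpscan") / "fixtures" / name)


def load_table(number: int) -> list[MarkerRecord]:
    """Records of one packaged marker table (1-7)."""
    if number not in TABLE_NUMBERS:
        raise ValueError(f"table number must be in {TABLE_NUMBERS}")
    return parse_marker_table(data_path(f"table{number}.tsv"))


def load_all_tables() -> list[MarkerRecord]:
    """All packaged marker rows, tables 1-7 concatenated in order."""
    records: list[MarkerRecord] = []
    for number in TABLE_NUMBERS:
        records.extend(load_table(number))
    return records


@functools.lru_cache(maxsize=1)
def named_inserts() -> dict[str, dict[str, str]]:
    """Per-gene dictionary resolving symbolic alleles such as ``18bp``."""
    with open(data_path("named_inserts.yaml"), encoding="utf-8") as handle:
        data = yaml.safe_load(handle)
    return {gene: {k: v.upper() for k, v in table.items()}
            for gene, table in data["inserts"].items()}
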