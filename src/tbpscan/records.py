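"""Shared enumerations and the marker-table row type.

A marker record is one row of the candidate-marker tables: the variant in
flank/allele notation, the predicted dissociation constants of the TBP-DNA
complex for both alleles, and the allele-comparison verdict (direction,
Z-score, significance bin, heuristic rank).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

from .errors import InsertResolutionError

#: Discrete significance levels used in the tables, best to worst.
ALPHA_LEVELS: tuple[float, ...] = (1e-6, 1e-3, 1e-2, 0.05, 1.0)


class Delta(Enum):
    """Predicted change of gene-product abundance in minor-allele carriers.

    Higher TBP-promoter affinity means more transcript, so a K_D increase
    maps to ``DEFICIENCY`` and a K_D decrease to ``EXCESS``.
    """

    DEFICIENCY = "↓"
    EXCESS = "↑"
    NORM = "="

    @classmethod
    def parse(cls, text: str) -> "Delta":
        aliases = {
            "↓": cls.DEFICIENCY, "down": cls.DEFICIENCY, "deficiency": cls.DEFICIENCY,
            "↑": cls.EXCESS, "up": cls.EXCESS, "excess": cls.EXCESS,
            "=": cls.NORM, "norm": cls.NORM,
        }
        try:
            return aliases[text.strip().lower()]
        except KeyError:
            raise ValueError(f"unknown direction symbol: {text!r}") from None


class Rank(Enum):
    """Heuristic priority of a candidate marker, best (A) to worst (E)."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"
    E = "E"

    @classmethod
    def parse(cls, text: str) -> "Rank":
        try:
            return cls[text.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown rank symbol: {text!r}") from None


def parse_alpha(text: str) -> float:
    value = float(text)
    for level in ALPHA_LEVELS:
        if math.isclose(value, level, rel_tol=1e-9):
            return level
    raise ValueError(f"alpha {text!r} is not one of the discrete levels {ALPHA_LEVELS}")


def format_alpha(alpha: float) -> str:
    if alpha >= 0.05:
        return "1" if alpha == 1.0 else "0.05"
    return f"{alpha:.0e}".replace("e-0", "e-0")


def _resolve_allele(allele: str, gene: str, inserts: Mapping[str, Mapping[str, str]] | None) -> str:
    """Return the concrete sequence for an allele field.

    ``-`` denotes an empty allele; a comma-separated list denotes several
    minor alleles sharing one table row, of which the first is scored; a
    token such as ``18bp`` is looked up in the per-gene insert dictionary.
    """
    allele = allele.strip()
    if allele in ("-", ""):
        return ""
    allele = allele.split(",")[0].strip()
    if all(c in "ACGTacgt" for c in allele):
        return allele.upper()
    if inserts is None:
        raise InsertResolutionError(f"no insert dictionary to resolve {allele!r}")
    table = inserts.get(gene, inserts.get("*", {}))
    try:
        return table[allele].upper()
    except KeyError:
        raise InsertResolutionError(f"unknown insert {allele!r} for gene {gene!r}") from None


@dataclass
class MarkerRecord:
    """One annotated row of a candidate-marker table."""

    gene_symbol: str
    variant_id: str
    flank5: str
    wt_allele: str
    mut_allele: str
    flank3: str
    kd_wt_nM: float | None
    kd_mut_nM: float | None
    delta: Delta
    z: float | None
    alpha: float | None
    rank: Rank | None
    annotation: str = ""
    flags: tuple[str, ...] = field(default_factory=tuple)

    def wt_sequence(self, inserts: Mapping[str, Mapping[str, str]] | None = None) -> str:
        """Flank5 + ancestral allele + flank3, inserts resolved, uppercase."""
        return (self.flank5.upper()
                + _resolve_allele(self.wt_allele, self.gene_symbol, inserts)
                + self.flank3.upper())

    def mut_sequence(self, inserts: Mapping[str, Mapping[str, str]] | None = None) -> str:
        """Flank5 + minor allele + flank3 (first allele of a comma list)."""
        return (self.flank5.upper()
                + _resolve_allele(self.mut_allele, self.gene_symbol, inserts)
                + self.flank3.upper())

    def with_flag(self, flag: str) -> "MarkerRecord":
        return replace(self, flags=self.flags + (flag,))

    def consistent(self) -> bool:
        """Check the row's internal invariants.

        Rank must follow the significance bin (1e-6 -> A ... 1 -> E), a
        ``norm`` direction must coincide with alpha = 1, and a directional
        call must agree with the sign of the K_D change. Rows carrying
        transcription flags are exempt from the check they are flagged for.
        """
        exempt = set(self.flags)
        if self.alpha is None or self.delta is None:
            return "incomplete" in exempt
        if "rank_mismatch" not in exempt and self.rank is not None:
            expected = dict(zip(ALPHA_LEVELS, Rank))
            if expected[self.alpha] is not self.rank:
                return False
        if "delta_at_alpha1" not in exempt:
            if (self.delta is Delta.NORM) != (self.alpha == 1.0):
                return False
        if "delta_sign_conflict" not in exempt and self.delta is not Delta.NORM:
            if self.kd_wt_nM is not None and self.kd_mut_nM is not None:
                diff = self.kd_mut_nM - self.kd_wt_nM
                if self.delta is Delta.DEFICIENCY and diff < 0:
                    return False
                if self.delta is Delta.EXCESS and diff > 0:
                    return False
        return True
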