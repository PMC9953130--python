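"""Decoy-set screening statistics: Güner–Henry score and enrichment factor.

For a database of D molecules containing A actives, a screen retrieving Ht
hits of which Ha are active is summarized by

    GH = [Ha (3A + Ht) / (4 Ht A)] * [1 - (Ht - Ha) / (D - A)]
    EF = (Ha / Ht) / (A / D)

GH approaches 1 for ideal retrieval and 0 when no active is retrieved; EF is
the active concentration among hits relative to the whole database, bounded
by D/A. Yield of actives (100·Ha/Ht), ratio of actives (100·Ha/A), and the
false negative/positive counts (A−Ha, Ht−Ha) complete the report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .structio import SmallMolecule
from .screening import MappingParams, screen_library
from .pharmacophore import PharmacophoreModel

__all__ = ["DecoyLabels", "ScreeningStats", "compute_stats", "validate_model"]

ACTIVE_IC50_NM = 100.0
INACTIVE_IC50_NM = 1000.0


@dataclass
class DecoyLabels:
    """Per-molecule activity labels for a decoy test set.

    Built either from explicit labels or from IC50 values: active below
    100 nM, inactive above 1000 nM; intermediate compounds are excluded at
    load time.
    """

    labels: dict[str, str]  # name -> "active" | "inactive"

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {"active", "inactive"}
        if bad:
            raise ValueError(f"invalid labels: {sorted(bad)}")

    @property
    def n_active(self) -> int:
        return sum(1 for v in self.labels.values() if v == "active")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, name: str) -> str:
        return self.labels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.labels

    @classmethod
    def from_ic50(cls, ic50_nM: dict[str, float]) -> "DecoyLabels":
        labels = {}
        for name, val in ic50_nM.items():
            if val < ACTIVE_IC50_NM:
                labels[name] = "active"
            elif val > INACTIVE_IC50_NM:
                labels[name] = "inactive"
            # 100 <= IC50 <= 1000 nM: ambiguous potency, excluded
        return cls(labels)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DecoyLabels":
        """Load labels from CSV with columns (name, ic50_nM) or (name, label)."""
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if "name" not in cols:
            raise ValueError("labels CSV needs a 'name' column")
        if "label" in cols:
            return cls(dict(zip(df[cols["name"]].astype(str),
                                df[cols["label"]].astype(str))))
        if "ic50_nm" in cols:
            return cls.from_ic50(dict(zip(df[cols["name"]].astype(str),
                                          df[cols["ic50_nm"]].astype(float))))
        raise ValueError("labels CSV needs a 'label' or 'ic50_nM' column")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"name": list(self.labels),
                      "label": list(self.labels.values())}
                     ).to_csv(path, index=False)


@dataclass(frozen=True)
class ScreeningStats:
    """All decoy-screen validation quantities."""

    D: int
    A: int
    Ht: int
    Ha: int
    yield_pct: float
    ratio_pct: float
    fn: int
    fp: int
    gh: float
    ef: float

    def to_frame(self) -> pd.DataFrame:
        """Validation report with the standard row names."""
        rows = [
            ("Total no. of molecules in the database (D)", self.D),
            ("Total number of active molecules in the database (A)", self.A),
            ("Total number of retrieved hits (Ht)", self.Ht),
            ("Number of active molecules in the retrieved hits (Ha)", self.Ha),
            ("% Yield of actives [(Ha/Ht) x 100]", f"{self.yield_pct:.2f}%"),
            ("% Ratio of actives [(Ha/A) x 100]", f"{self.ratio_pct:.2f}%"),
            ("False-negative [A-Ha]", self.fn),
            ("False-positive [Ht-Ha]", self.fp),
            ("Goodness of fit", f"{self.gh:.2f}"),
            ("Enrichment factor (EF)", f"{self.ef:.2f}"),
        ]
        return pd.DataFrame(rows, columns=["Parameters", "Calculated Values"])


def compute_stats(D: int, A: int, Ht: int, Ha: int) -> ScreeningStats:
    """Compute all validation statistics from the four screen counts.

    Raises a validation error naming the violated count invariant; the
    degenerate cases Ht = 0 and D = A return 0 for the affected ratios with
    a warning.
    """
    if D < 0 or A < 0 or Ht < 0 or Ha < 0:
        raise ValueError("counts must be non-negative")
    if A > D:
        raise ValueError(f"A ({A}) cannot exceed D ({D})")
    if Ht > D:
        raise ValueError(f"Ht ({Ht}) cannot exceed D ({D})")
    if Ha > min(Ht, A):
        raise ValueError(f"Ha ({Ha}) cannot exceed min(Ht, A) = {min(Ht, A)}")
    if Ht - Ha > D - A:
        raise ValueError(
            f"fp = Ht - Ha ({Ht - Ha}) cannot exceed the number of "
            f"inactives D - A ({D - A})")

    if Ht == 0:
        warnings.warn("Ht = 0: yield, GH and EF defined as 0")
        yield_pct = gh = ef = 0.0
    else:
        yield_pct = 100.0 * Ha / Ht
        if A == 0:
            warnings.warn("A = 0: GH and EF defined as 0")
            gh = ef = 0.0
        elif D == A:
            warnings.warn("D = A: GH penalty term undefined, GH defined as 0")
            gh = 0.0
            ef = (Ha / Ht) / (A / D)
        else:
            gh = (Ha * (3 * A + Ht) / (4.0 * Ht * A)) \
                * (1.0 - (Ht - Ha) / float(D - A))
            ef = (Ha / Ht) / (A / float(D))
    ratio_pct = 100.0 * Ha / A if A else 0.0
    return ScreeningStats(D=D, A=A, Ht=Ht, Ha=Ha, yield_pct=yield_pct,
                          ratio_pct=ratio_pct, fn=A - Ha, fp=Ht - Ha,
                          gh=gh, ef=ef)


def validate_model(library: list[SmallMolecule], labels: DecoyLabels,
                   model: PharmacophoreModel,
                   params: MappingParams | None = None) -> ScreeningStats:
    """Screen a labeled decoy set (no drug-likeness filter) and score it.

    Every library molecule must be labeled; the decoy set is screened as-is
    and Ht/Ha counted against the labels.
    """
    unlabeled = [m.name for m in library if m.name not in labels]
    if unlabeled:
        raise ValueError(f"unlabeled molecules: {unlabeled[:5]}"
                         + ("..." if len(unlabeled) > 5 else ""))
    hits, _stats = screen_library(library, model, params, apply_rof=False)
    Ht = len(hits)
    Ha = sum(1 for mol, _res in hits if labels[mol.name] == "active")
    return compute_stats(D=len(library), A=labels.n_active, Ht=Ht, Ha=Ha)
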