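"""Experimental solubility/hydrophobicity scales and correlation analysis.

The embedded table pairs, for 18 homotetrapeptide systems (all natural
amino acids except Gly and Cys), the simulation-derived aggregation
metrics — window-averaged mean cluster size and averaged monomer count —
with five experimental per-residue scales:

* individual amino-acid solubility in water (g/kg),
* the Kyte–Doolittle hydropathy index,
* a hydrophilicity scale (kcal/mol),
* a transfer hydrophobicity scale (kcal/mol),
* a protein-solubility contribution scale from peptide-tag measurements
  (mg/ml), unavailable for eight residues.

Pearson correlations over pairwise-complete rows reproduce the published
R values relating aggregation to each scale; named exclusion presets
cover the documented variants (amino-acid solubility without the Pro
outlier, protein solubility without Asn).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "builtin_scales",
    "CorrelationSpec",
    "pearson",
    "correlation_report",
    "SCALE_COLUMNS",
    "EXCLUSION_PRESETS",
]

#: metric/scale columns of the embedded table
SCALE_COLUMNS = [
    "averaged_mcs",
    "aa_solubility",
    "hydropathy",
    "hydrophilicity",
    "hydrophobicity",
    "protein_solubility",
    "averaged_monomers",
]

# residue, averaged MCS, aa solubility (g/kg), hydropathy, hydrophilicity
# (kcal/mol), hydrophobicity (kcal/mol), protein solubility (mg/ml),
# averaged monomers; NaN where the source prints a blank or "Na"
_TABLE = [
    ("Ile", 25.1, 34.2, 4.5, 0.2, 2.5, 0.1, 0.6),
    ("Leu", 26.2, 23.8, 3.8, 0.1, 1.8, np.nan, 0.3),
    ("Val", 22.6, 88.0, 4.2, 0.4, 1.5, np.nan, 1.2),
    ("Gln", 24.4, 42.0, -3.5, 11.8, -0.3, 4.7, 1.2),
    ("Asn", 19.0, 25.1, -3.5, 12.1, -0.2, 15.4, 3.9),
    ("Thr", 12.0, 90.6, -0.7, 7.3, 0.4, np.nan, 5.4),
    ("Ser", 6.2, 250.0, -0.8, 7.5, -0.3, 4.6, 9.0),
    ("Ala", 3.4, 166.9, 1.8, 0.5, 0.5, np.nan, 13.7),
    ("Pro", 2.6, 1625.0, -1.6, np.nan, -3.3, 2.0, 12.9),
    ("Asp", 1.1, 5.4, -3.5, 13.3, -7.4, 14.2, 25.4),
    ("Glu", 1.0, 8.6, -3.5, 12.6, -9.9, 11.0, 26.5),
    ("Arg", 1.0, 182.6, -4.5, 22.3, -11.2, 8.9, 24.6),
    ("Lys", 1.1, 5.8, -3.9, 11.9, -4.2, 17.0, 25.4),
    ("Phe", 23.1, 27.9, 2.8, 3.2, 2.5, np.nan, 0.4),
    ("Tyr", 21.8, 0.5, -1.3, 8.5, 2.3, np.nan, 1.4),
    ("Trp", 24.8, 13.2, -0.9, 8.3, 3.4, np.nan, 0.7),
    ("His", 25.1, 43.5, -3.2, 12.6, 0.5, 0.9, 0.5),
    ("Met", 24.8, 56.0, 1.9, 3.9, 1.3, np.nan, 0.7),
]

#: documented exclusion variants for specific scale columns
EXCLUSION_PRESETS: dict[str, list[str]] = {
    "exclude_Pro": ["Pro"],
    "exclude_Asn": ["Asn"],
}


def builtin_scales() -> pd.DataFrame:
    """The embedded 18-residue metric/scale table (a fresh copy)."""
    df = pd.DataFrame(_TABLE, columns=["residue"] + SCALE_COLUMNS)
    return df.set_index("residue")


@dataclass(frozen=True)
class CorrelationSpec:
    """One correlation request: columns, exclusions, pairwise-complete."""

    x_column: str
    y_column: str
    exclude: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.x_column == self.y_column:
            raise ValueError("x and y columns must differ")


@dataclass(frozen=True)
class PearsonResult:
    r: float
    n_used: int
    residues_used: tuple[str, ...]


def pearson(spec: CorrelationSpec, table: pd.DataFrame | None = None) -> PearsonResult:
    """Pearson r over pairwise-complete, non-excluded rows.

    Requires at least 3 complete pairs after exclusions.
    """
    df = builtin_scales() if table is None else table
    sub = df.drop(index=[r for r in spec.exclude if r in df.index])
    sub = sub[[spec.x_column, spec.y_column]].dropna()
    if len(sub) < 3:
        raise ValueError(f"only {len(sub)} complete pairs; need at least 3")
    r, _ = stats.pearsonr(sub[spec.x_column], sub[spec.y_column])
    return PearsonResult(r=float(r), n_used=len(sub), residues_used=tuple(sub.index))


def spearman(spec: CorrelationSpec, table: pd.DataFrame | None = None) -> PearsonResult:
    """Rank (Spearman) analogue of :func:`pearson`; diagnostic only."""
    df = builtin_scales() if table is None else table
    sub = df.drop(index=[r for r in spec.exclude if r in df.index])
    sub = sub[[spec.x_column, spec.y_column]].dropna()
    if len(sub) < 3:
        raise ValueError(f"only {len(sub)} complete pairs; need at least 3")
    r, _ = stats.spearmanr(sub[spec.x_column], sub[spec.y_column])
    return PearsonResult(r=float(r), n_used=len(sub), residues_used=tuple(sub.index))


def correlation_report(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Correlations of both aggregation metrics against every scale column.

    One row per (metric, scale, variant): the plain pairwise-complete r
    plus the documented exclusion variants (amino-acid solubility without
    Pro, protein solubility without Asn).  ``r_2dp`` rounds to the
    precision the reference values are printed at.
    """
    df = builtin_scales() if table is None else table
    metrics = ["averaged_mcs", "averaged_monomers"]
    variants = {
        "aa_solubility": [(), tuple(EXCLUSION_PRESETS["exclude_Pro"])],
        "protein_solubility": [(), tuple(EXCLUSION_PRESETS["exclude_Asn"])],
    }
    rows = []
    for metric in metrics:
        for col in SCALE_COLUMNS:
            if col == metric:
                continue
            for excl in variants.get(col, [()]):
                res = pearson(CorrelationSpec(metric, col, excl), df)
                rows.append(
                    {
                        "metric": metric,
                        "scale": col,
                        "exclude": "/".join(excl) if excl else "",
                        "r": res.r,
                        "r_2dp": round(res.r, 2),
                        "n_used": res.n_used,
                    }
                )
    return pd.DataFrame(rows)
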