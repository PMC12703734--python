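"""Experimental-affinity conversion and correlation/ΔΔG benchmarking.

Dissociation constants (and K_i/IC50 used as K_D surrogates) convert to
binding free energies via dG = R T ln(K_D); predictions are judged by the
squared Pearson correlation (equivalently the unadjusted R² of the
univariate least-squares fit) against experiment, optionally after
excluding outlier complexes or on all-pairs ΔΔG differences where
constant offsets cancel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gbneck2 import GAS_CONSTANT


@dataclass
class AffinityRecord:
    complex_id: str
    affinity_molar: float | None = None
    kind: str = "KD"                 # KD | Ki | IC50 | dG
    dg_kcal_mol: float | None = None
    temperature: float = 298.15

    def __post_init__(self) -> None:
        has_k = self.affinity_molar is not None
        has_g = self.dg_kcal_mol is not None
        if has_k == has_g:
            raise ValueError("exactly one of affinity or dG must be given")
        if has_k and self.affinity_molar <= 0:
            raise ValueError("affinity constant must be positive")


def affinity_to_dg(record: AffinityRecord) -> float:
    """dG = R T ln(K); direct dG records pass through unchanged."""
    if record.dg_kcal_mol is not None:
        return float(record.dg_kcal_mol)
    return float(GAS_CONSTANT * record.temperature * np.log(record.affinity_molar))


def load_affinity_table(path: str | Path | None = None) -> pd.DataFrame:
    """Experimental benchmark table (default: the packaged 20-complex set
    of protein–protein complexes with experimental dG in kcal/mol)."""
    if path is None:
        with resources.files("mnmgbsa.data").joinpath("table1_affinities.csv").open() as fh:
            return pd.read_csv(fh)
    df = pd.read_csv(path)
    if "dg_exp_kcal_mol" not in df.columns:
        # delimited table with (pdb_id, value, kind, temperature)
        dgs = []
        for _, row in df.iterrows():
            if str(row["kind"]).lower() in ("dg", "deltag"):
                rec = AffinityRecord(row["pdb_id"], dg_kcal_mol=float(row["value"]))
            else:
                rec = AffinityRecord(row["pdb_id"], affinity_molar=float(row["value"]),
                                     kind=row["kind"],
                                     temperature=float(row.get("temperature", 298.15)))
            dgs.append(affinity_to_dg(rec))
        df["dg_exp_kcal_mol"] = dgs
    return df


@dataclass
class CorrelationReport:
    n: int
    r_squared: float
    slope: float
    intercept: float
    residuals: dict[str, float]
    excluded: list[str]

    def summary(self) -> str:
        lines = [
            f"n = {self.n}",
            f"r^2 = {self.r_squared:.3f}",
            f"fit: predicted = {self.slope:.3f} * experimental + {self.intercept:.3f}",
        ]
        if self.excluded:
            lines.append("excluded: " + ", ".join(self.excluded))
        return "\n".join(lines) + "\n"


def _paired(experimental: dict[str, float], predicted: dict[str, float],
            exclude: list[str] | None) -> tuple[list[str], np.ndarray, np.ndarray]:
    exclude = set(exclude or [])
    ids = [i for i in experimental if i in predicted and i not in exclude]
    x = np.array([experimental[i] for i in ids])
    y = np.array([predicted[i] for i in ids])
    return ids, x, y


def correlation_report(experimental: dict[str, float],
                       predicted: dict[str, float],
                       exclude: list[str] | None = None) -> CorrelationReport:
    """Least-squares line and squared Pearson correlation of predictions
    against experiment, pairing by complex id."""
    ids, x, y = _paired(experimental, predicted, exclude)
    if len(ids) < 3:
        raise ValueError(f"need >= 3 paired complexes, have {len(ids)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in a series; correlation undefined")
    fit = stats.linregress(x, y)
    resid = {i: float(yy - (fit.slope * xx + fit.intercept))
             for i, xx, yy in zip(ids, x, y)}
    return CorrelationReport(n=len(ids), r_squared=float(fit.rvalue ** 2),
                             slope=float(fit.slope), intercept=float(fit.intercept),
                             residuals=resid, excluded=sorted(set(exclude or [])))


def ddg_report(experimental: dict[str, float], predicted: dict[str, float],
               exclude: list[str] | None = None,
               pairing: str = "all-unordered-pairs",
               reference: str | None = None) -> CorrelationReport:
    """Correlation over relative binding free energies ΔΔG.

    ``all-unordered-pairs`` forms ΔΔG_ij = ΔG_i − ΔG_j for every unordered
    complex pair; ``reference`` mode differences every complex against one
    reference id.  Absolute offsets common to a series cancel either way.
    """
    ids, x, y = _paired(experimental, predicted, exclude)
    if len(ids) < 3:
        raise ValueError(f"need >= 3 paired complexes, have {len(ids)}")
    if pairing == "all-unordered-pairs":
        pair_ids = list(combinations(range(len(ids)), 2))
    elif pairing == "reference":
        if reference not in ids:
            raise ValueError(f"reference {reference!r} not among paired ids")
        ref = ids.index(reference)
        pair_ids = [(i, ref) for i in range(len(ids)) if i != ref]
    else:
        raise ValueError(f"unknown pairing {pairing!r}")
    dx = np.array([x[i] - x[j] for i, j in pair_ids])
    dy = np.array([y[i] - y[j] for i, j in pair_ids])
    if np.std(dx) == 0 or np.std(dy) == 0:
        raise ValueError("zero variance in a ΔΔG series; correlation undefined")
    fit = stats.linregress(dx, dy)
    resid = {f"{ids[i]}-{ids[j]}": float(yy - (fit.slope * xx + fit.intercept))
             for (i, j), xx, yy in zip(pair_ids, dx, dy)}
    return CorrelationReport(n=len(pair_ids), r_squared=float(fit.rvalue ** 2),
                             slope=float(fit.slope), intercept=float(fit.intercept),
                             residuals=resid, excluded=sorted(set(exclude or [])))
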