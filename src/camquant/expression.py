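"""Relative gene expression by the comparative Cq (ΔΔCq) method.

Each sample's target-gene quantification cycle is normalized against the
arithmetic mean of two housekeeping-gene Cq means (equivalent to
geometric-mean normalization of the underlying quantities):

    ΔCq  = mean Cq(target) - mean(mean Cq(HK1), mean Cq(HK2))
    ΔΔCq = mean ΔCq(treated) - mean ΔCq(control)
    fold = E^(-ΔΔCq)          with amplification efficiency E = 2

so fold change 1 corresponds to the untreated controls. A gene is flagged as
changed only under a dual cut-off: |log2 fold| > 1 (fold above 2 or below
0.5) AND p < 0.05 from a two-sided Welch t-test on the per-sample ΔCq values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sample_id", "condition", "gene", "replicate", "cq")
DEFAULT_EFFICIENCY = 2.0
FOLD_CUTOFF = 2.0
P_CUTOFF = 0.05


@dataclass(frozen=True)
class FoldChangeResult:
    gene: str
    delta_delta_cq: float
    fold_change: float
    p_value: float  # NaN when not computable (singleton groups)
    n_treated: int
    n_control: int
    flagged: bool = False


def load_cq_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format Cq table (CSV)."""
    df = pd.read_csv(path)
    return validate_cq_table(df)


def validate_cq_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Cq table missing columns: {missing}")
    cq = df["cq"].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(cq)) or (cq <= 0).any():
        raise ValueError("Cq values must be finite and > 0")
    reps = df.groupby(["sample_id", "gene"])["replicate"].count()
    if (reps != 3).any():
        logger.warning(
            "non-triplicate Cq structure for %d sample/gene combinations",
            int((reps != 3).sum()),
        )
    return df


def delta_cq(
    table: pd.DataFrame, target_gene: str, housekeeping: tuple[str, str]
) -> pd.DataFrame:
    """Per-sample ΔCq of ``target_gene`` against two housekeeping genes.

    Replicates are averaged per gene first; the housekeeping reference is the
    arithmetic mean of the two housekeeping Cq means. Returns a frame with
    sample_id, condition and delta_cq.
    """
    if len(housekeeping) != 2:
        raise ValueError("exactly 2 housekeeping genes are required")
    gene_means = (
        table.groupby(["sample_id", "condition", "gene"])["cq"].mean().reset_index()
    )
    rows = []
    for (sample, condition), grp in gene_means.groupby(["sample_id", "condition"]):
        by_gene = dict(zip(grp["gene"], grp["cq"]))
        for hk in housekeeping:
            if hk not in by_gene:
                raise ValueError(f"sample {sample!r} is missing housekeeping gene {hk!r}")
        if target_gene not in by_gene:
            continue
        hk_ref = (by_gene[housekeeping[0]] + by_gene[housekeeping[1]]) / 2.0
        rows.append(
            {"sample_id": sample, "condition": condition,
             "delta_cq": by_gene[target_gene] - hk_ref}
        )
    return pd.DataFrame(rows, columns=["sample_id", "condition", "delta_cq"])


def fold_change(
    delta_cq_treated: np.ndarray,
    delta_cq_control: np.ndarray,
    gene: str = "",
    efficiency: float = DEFAULT_EFFICIENCY,
) -> FoldChangeResult:
    """ΔΔCq fold change of the treated group relative to control.

    p comes from a two-sided Welch t-test on the per-sample ΔCq values;
    singleton groups still yield a fold change but a missing p.
    """
    treated = np.asarray(delta_cq_treated, dtype=np.float64)
    control = np.asarray(delta_cq_control, dtype=np.float64)
    if treated.size < 1 or control.size < 1:
        raise ValueError("both groups need at least one sample")
    ddcq = float(treated.mean() - control.mean())
    fold = float(efficiency ** (-ddcq))
    if treated.size >= 2 and control.size >= 2:
        p = float(stats.ttest_ind(treated, control, equal_var=False).pvalue)
    else:
        p = math.nan
    return FoldChangeResult(
        gene=gene, delta_delta_cq=ddcq, fold_change=fold, p_value=p,
        n_treated=int(treated.size), n_control=int(control.size),
    )


def apply_cutoff(
    result: FoldChangeResult,
    fold_cut: float = FOLD_CUTOFF,
    p_cut: float = P_CUTOFF,
) -> bool:
    """Dual significance rule: |log2 fold| > log2(fold_cut) AND p < p_cut.

    Both comparisons are strict; down-regulation is treated symmetrically
    (fold below 1/fold_cut also passes the magnitude clause). A missing p
    never flags, with a logged note.
    """
    if math.isnan(result.p_value):
        logger.info("gene %s: p value missing, not flagged", result.gene or "<unnamed>")
        return False
    magnitude_ok = abs(math.log2(result.fold_change)) > math.log2(fold_cut)
    return magnitude_ok and result.p_value < p_cut


def relative_expression(
    table: pd.DataFrame,
    housekeeping: tuple[str, str],
    treated: str = "CAP",
    control: str = "UT",
    efficiency: float = DEFAULT_EFFICIENCY,
) -> pd.DataFrame:
    """Fold change + dual cut-off for every target gene in a validated Cq table."""
    validate_cq_table(table)
    genes = [g for g in table["gene"].unique() if g not in housekeeping]
    rows = []
    for gene in genes:
        dcq = delta_cq(table, gene, housekeeping)
        res = fold_change(
            dcq.loc[dcq["condition"] == treated, "delta_cq"].to_numpy(),
            dcq.loc[dcq["condition"] == control, "delta_cq"].to_numpy(),
            gene=gene,
            efficiency=efficiency,
        )
        rows.append(
            {
                "gene": gene,
                "delta_delta_cq": res.delta_delta_cq,
                "fold_change": res.fold_change,
                "p_value": res.p_value,
                "n_treated": res.n_treated,
                "n_control": res.n_control,
                "flagged": apply_cutoff(res),
            }
        )
    return pd.DataFrame(rows)
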