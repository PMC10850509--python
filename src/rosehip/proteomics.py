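"""IP-MS downstream computation: PSM aggregation, peptide-level
differential enrichment, and the total-protein-enrichment score.

PSM reporter intensities are median-aggregated into unique peptides
(peptides matching multiple master proteins are discarded).  Per-protein
enrichment of IP over control channels is computed by a peptide-level
statistic — a two-sample t on log2 intensities with an optional pooled
variance floor, combined across a protein's peptides through the median
order statistic's exact Beta null.  This is a self-contained surrogate
for peptide-level enrichment-curve analysis: it follows the same outline
(peptide t-type statistic, order-statistic p combination, BH over
proteins) and accepts precomputed protein tables so an external upstream
can be slotted in unchanged.

The ranking score is ``-log10(q) * (2 * fold_enrichment)`` with the fold
on the linear scale.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_TINY = np.finfo(float).tiny


def aggregate_psm_to_peptide(
    psms: pd.DataFrame, channel_cols: list[str]
) -> pd.DataFrame:
    """Median-aggregate PSMs into unique (protein, peptide) rows.

    Peptides whose sequence maps to more than one protein are excluded,
    keeping only peptides assigned to a unique master protein.  The
    median is per channel; even PSM counts use the mean of the two middle
    values.
    """
    required = {"protein_id", "peptide"} | set(channel_cols)
    missing = required - set(psms.columns)
    if missing:
        raise ValueError(f"PSM table missing columns {sorted(missing)}")
    n_proteins = psms.groupby("peptide")["protein_id"].nunique()
    shared = set(n_proteins.index[n_proteins > 1])
    if shared:
        warnings.warn(
            f"excluding {len(shared)} peptides shared between proteins"
        )
        psms = psms[~psms["peptide"].isin(shared)]
    out = (
        psms.groupby(["protein_id", "peptide"], sort=True)[channel_cols]
        .median()
        .reset_index()
    )
    return out


def _offset_zeros(values: np.ndarray) -> np.ndarray:
    """Replace zeros by half the smallest nonzero value (per matrix)."""
    nonzero = values[values > 0]
    if nonzero.size == 0:
        return values
    floor = nonzero.min() / 2.0
    out = values.copy()
    out[out == 0] = floor
    return out


def protein_differential(
    peptides: pd.DataFrame,
    ip_channels: list[str],
    control_channels: list[str],
    variance_floor_quantile: float = 0.0,
    zero_offset: bool = True,
) -> pd.DataFrame:
    """Per-protein fold enrichment, p-value and BH q-value.

    Per peptide: two-sample t on log2 channel intensities (IP vs control)
    with pooled variance, optionally floored at the given quantile of all
    peptide variances (a guard against near-zero spread; 0 disables the
    floor so null p-values stay exactly uniform).  Per protein: fold
    enrichment is the median peptide linear ratio; the protein p-value is
    the median peptide p assessed against its exact order-statistic null,
    Beta(k+1, n-k) for n peptides with k = floor(n/2).  q-values are BH
    step-up over proteins.
    """
    for group, cols in (("IP", ip_channels), ("control", control_channels)):
        missing = set(cols) - set(peptides.columns)
        if missing:
            raise ValueError(f"{group} channels absent: {sorted(missing)}")
    ip = peptides[ip_channels].to_numpy(dtype=float)
    ctrl = peptides[control_channels].to_numpy(dtype=float)
    all_zero = (ip.sum(axis=1) == 0) & (ctrl.sum(axis=1) == 0)
    if all_zero.any():
        warnings.warn(
            f"excluding {int(all_zero.sum())} peptides with all-zero intensities"
        )
        peptides = peptides.loc[~all_zero]
        ip, ctrl = ip[~all_zero], ctrl[~all_zero]
    if zero_offset:
        ip = _offset_zeros(ip)
        ctrl = _offset_zeros(ctrl)
    log_ip = np.log2(ip)
    log_ctrl = np.log2(ctrl)
    n1, n2 = log_ip.shape[1], log_ctrl.shape[1]
    diff = log_ip.mean(axis=1) - log_ctrl.mean(axis=1)

    if n1 >= 2 and n2 >= 2:
        ss = ((log_ip - log_ip.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
            (log_ctrl - log_ctrl.mean(axis=1, keepdims=True)) ** 2
        ).sum(axis=1)
        df = n1 + n2 - 2
        s2 = ss / df
    else:
        # moderated fallback: single-channel groups borrow the global
        # median peptide variance; df treated as large
        warnings.warn("fewer than 2 channels in a group; using global variance")
        s2 = np.full(len(diff), max(np.var(diff), 1e-8))
        df = max(len(diff) - 1, 1)
    if variance_floor_quantile > 0:
        floor = np.quantile(s2, variance_floor_quantile)
        s2 = np.maximum(s2, floor)
    s2 = np.maximum(s2, 1e-300)
    tstat = diff / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    pep_p = 2.0 * stats.t.sf(np.abs(tstat), df)

    table = peptides[["protein_id"]].copy()
    table["ratio"] = 2.0 ** diff
    table["p"] = pep_p

    rows = []
    for protein_id, grp in table.groupby("protein_id", sort=True):
        n = len(grp)
        fold = float(np.median(grp["ratio"]))
        k = n // 2
        p_sorted = np.sort(grp["p"].to_numpy())
        p_med = p_sorted[k]  # (k+1)-th smallest: the upper median for even n
        # exact null of the (k+1)-th order statistic of n uniforms
        p_prot = float(stats.beta.cdf(p_med, k + 1, n - k))
        rows.append(
            {
                "protein_id": protein_id,
                "fold_enrichment": fold,
                "p_value": p_prot,
                "n_peptides": n,
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    _, q, _, _ = multipletests(pvalues, method="fdr_bh")
    return q


def enrichment_score_and_rank(table: pd.DataFrame) -> pd.DataFrame:
    """Total protein enrichment: -log10(q) * (2 * fold), ranked descending.

    Ties break by fold enrichment then protein_id.  q = 0 is clamped to
    the smallest positive float with a warning.
    """
    required = {"protein_id", "fold_enrichment", "q_value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"protein table missing {sorted(missing)}")
    out = table.copy()
    q = out["q_value"].to_numpy(dtype=float)
    if (q < 0).any() or (q > 1).any():
        raise ValueError("q_value outside [0, 1]")
    if (q == 0).any():
        warnings.warn("q_value of 0 clamped to smallest positive float")
        q = np.where(q == 0, _TINY, q)
    out["enrichment_score"] = -np.log10(q) * (2.0 * out["fold_enrichment"])
    out = out.sort_values(
        ["enrichment_score", "fold_enrichment", "protein_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out
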