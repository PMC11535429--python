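"""UHP/DHP/type-0 classification of cassette events.

For every event and tissue an ordinary least-squares line

    Y(g) ~ b0 + b1 * psi(e)

is fitted over the tissue's samples (samples with undefined psi dropped
pairwise).  The two-sided t-test p-value on b1 is corrected per tissue by
Benjamini-Hochberg.  An event is

* **UHP** if b1 > 0, adjusted p <= alpha, R^2 >= 0.5 and the gene's
  95th/5th expression-percentile ratio is >= 2;
* **DHP** the same with b1 < 0;
* **TYPE0** if the adjusted p is at least 0.5 (no evidence of coupling)
  while the event still shows the required expression variability;
* **UNCLASSIFIED** otherwise (filter failures, too few usable samples,
  constant psi, or adjusted p between alpha and the type-0 floor).

The same machinery reruns per donor to check that the direction of
coupling found in tissues is reproduced within individual donors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "classify_events",
    "cross_tissue_consistency",
    "donor_level_reclassification",
    "slope_vs_mean_expression",
    "marker_correlation",
    "split_by_poisson_mixture",
    "bh_adjust",
    "PoissonMixtureSplit",
]

_CLS_COLUMNS = [
    "event_id",
    "tissue",
    "n_samples",
    "beta0",
    "beta1",
    "p_raw",
    "p_adj",
    "r2",
    "ratio_95_5",
    "label",
    "reason",
]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def classify_events(
    table,
    filters: pd.DataFrame,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    type0_floor: float = 0.5,
    min_r2: float = 0.5,
    min_ratio: float = 2.0,
    group_col: str = "tissue",
    min_samples: int = 3,
) -> pd.DataFrame:
    """Fit the coupling regression per event per sample group and label.

    ``filters`` is the long-format report of
    :func:`~psicoupling.quantification.apply_variability_filters` computed
    with the same grouping.  Benjamini-Hochberg correction is applied
    within each group over all events actually fitted.  Events that fail
    the filters, have fewer than ``min_samples`` samples with defined psi,
    or constant psi, are reported UNCLASSIFIED with the reason recorded.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata else metadata
    groups = meta.loc[table.samples, group_col]
    filt = filters.set_index(["event_id", "tissue"])
    y_events = table.gene_expression_for_events()

    out_rows: list[dict] = []
    for group, cols in groups.groupby(groups).groups.items():
        cols = list(cols)
        psi = table.psi[cols].to_numpy()
        y = y_events[cols].to_numpy()
        fitted_idx: list[int] = []
        fitted: list[dict] = []
        for i, event_id in enumerate(table.psi.index):
            frow = filt.loc[(event_id, group)]
            ratio = float(frow["ratio_95_5"])
            base = {
                "event_id": event_id,
                "tissue": group,
                "beta0": np.nan,
                "beta1": np.nan,
                "p_raw": np.nan,
                "p_adj": np.nan,
                "r2": np.nan,
                "ratio_95_5": ratio,
            }
            mask = ~np.isnan(psi[i])
            n_use = int(mask.sum())
            base["n_samples"] = n_use
            if not bool(frow["passed"]):
                out_rows.append(
                    {**base, "label": "UNCLASSIFIED", "reason": "failed_filters"}
                )
                continue
            if n_use < min_samples:
                out_rows.append(
                    {**base, "label": "UNCLASSIFIED", "reason": "too_few_samples"}
                )
                continue
            x = psi[i, mask]
            if np.ptp(x) == 0:
                out_rows.append(
                    {**base, "label": "UNCLASSIFIED", "reason": "constant_psi"}
                )
                continue
            res = stats.linregress(x, y[i, mask])
            base.update(
                beta0=res.intercept,
                beta1=res.slope,
                p_raw=res.pvalue,
                r2=res.rvalue**2,
            )
            fitted_idx.append(len(out_rows))
            out_rows.append({**base, "label": None, "reason": "fitted"})
            fitted.append(base)

        if fitted:
            p_adj = bh_adjust(np.array([f["p_raw"] for f in fitted]))
            for j, row_idx in enumerate(fitted_idx):
                row = out_rows[row_idx]
                row["p_adj"] = p_adj[j]
                row["label"] = _label(
                    beta1=row["beta1"],
                    p_adj=p_adj[j],
                    r2=row["r2"],
                    ratio=row["ratio_95_5"],
                    alpha=alpha,
                    type0_floor=type0_floor,
                    min_r2=min_r2,
                    min_ratio=min_ratio,
                )

    return pd.DataFrame(out_rows, columns=_CLS_COLUMNS)


def _label(
    beta1: float,
    p_adj: float,
    r2: float,
    ratio: float,
    alpha: float,
    type0_floor: float,
    min_r2: float,
    min_ratio: float,
) -> str:
    ratio_ok = ratio >= min_ratio
    if p_adj <= alpha and r2 >= min_r2 and ratio_ok and beta1 != 0:
        return "UHP" if beta1 > 0 else "DHP"
    if p_adj >= type0_floor and ratio_ok:
        return "TYPE0"
    return "UNCLASSIFIED"


def cross_tissue_consistency(classifications: pd.DataFrame) -> pd.DataFrame:
    """Per-event tally of UHP/DHP calls across tissues; conflicts flagged."""
    rows = []
    for event_id, grp in classifications.groupby("event_id", sort=True):
        n_uhp = int((grp["label"] == "UHP").sum())
        n_dhp = int((grp["label"] == "DHP").sum())
        rows.append(
            {
                "event_id": event_id,
                "tissues_as_UHP": n_uhp,
                "tissues_as_DHP": n_dhp,
                "conflict": n_uhp > 0 and n_dhp > 0,
            }
        )
    return pd.DataFrame(
        rows, columns=["event_id", "tissues_as_UHP", "tissues_as_DHP", "conflict"]
    )


@dataclass
class DonorAgreement:
    report: pd.DataFrame       # per (event, donor) classification
    agreement_fraction: float  # direction agreement with tissue-level calls
    n_compared: int


def donor_level_reclassification(
    table,
    metadata: pd.DataFrame,
    tissue_classifications: pd.DataFrame,
    min_samples_per_donor: int = 20,
    **classify_kwargs,
) -> DonorAgreement:
    """Rerun filtering and classification grouping samples by donor.

    Only donors with at least ``min_samples_per_donor`` samples are
    considered.  The agreement fraction is computed over (event, donor)
    pairs called UHP/DHP whose event is also called UHP/DHP in at least
    one tissue: it is the fraction whose direction matches the tissue
    call (tissue calls are direction-consistent across tissues whenever
    there is no conflict).
    """
    from .quantification import apply_variability_filters

    meta = metadata.copy()
    counts = meta["donor"].value_counts()
    keep = counts[counts >= min_samples_per_donor].index
    meta = meta[meta["donor"].isin(keep)]
    if meta.empty:
        warnings.warn("no donor reaches the minimum sample count", stacklevel=2)
        return DonorAgreement(
            report=pd.DataFrame(columns=_CLS_COLUMNS),
            agreement_fraction=float("nan"),
            n_compared=0,
        )

    sub = _subset_table(table, list(meta["sample_id"]))
    donor_meta = meta[["sample_id", "donor"]].rename(columns={"donor": "tissue"})
    donor_filters = apply_variability_filters(sub, donor_meta)
    donor_cls = classify_events(
        sub, donor_filters, donor_meta, group_col="tissue", **classify_kwargs
    )

    tissue_dir = (
        tissue_classifications[
            tissue_classifications["label"].isin(["UHP", "DHP"])
        ]
        .groupby("event_id")["label"]
        .agg(lambda s: s.mode().iloc[0])
    )
    called = donor_cls[donor_cls["label"].isin(["UHP", "DHP"])]
    called = called[called["event_id"].isin(tissue_dir.index)]
    if called.empty:
        agreement = float("nan")
    else:
        agreement = float(
            (
                called["label"].to_numpy()
                == tissue_dir.loc[called["event_id"]].to_numpy()
            ).mean()
        )
    return DonorAgreement(
        report=donor_cls, agreement_fraction=agreement, n_compared=len(called)
    )


def _subset_table(table, samples: list[str]):
    from .quantification import PsiExpressionTable

    return PsiExpressionTable(
        psi=table.psi[samples],
        inc=table.inc[samples],
        exc=table.exc[samples],
        gene_expression=table.gene_expression[samples],
        event_gene=table.event_gene,
    )


def slope_vs_mean_expression(
    classifications: pd.DataFrame, table
) -> dict[str, float]:
    """Regress per-event |b1| on the gene's mean expression.

    Uses events called UHP or DHP in at least one tissue; the slope of the
    coupling line tracks the expression scale of the gene, so the fitted
    coefficient is expected near 1 when coupling acts multiplicatively.
    """
    called = classifications[classifications["label"].isin(["UHP", "DHP"])]
    if called["event_id"].nunique() < 2:
        raise ValueError("need at least 2 UHP/DHP events")
    slope_per_event = called.groupby("event_id")["beta1"].apply(
        lambda s: float(np.abs(s).mean())
    )
    y_events = table.gene_expression_for_events()
    mean_y = y_events.loc[slope_per_event.index].mean(axis=1)
    if np.ptp(mean_y.to_numpy()) == 0:
        raise ValueError("degenerate regression: all mean expressions equal")
    res = stats.linregress(mean_y.to_numpy(), slope_per_event.to_numpy())
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r": float(res.rvalue),
        "n_events": int(len(slope_per_event)),
    }


def marker_correlation(
    table, classifications: pd.DataFrame, marker_gene: str
) -> pd.DataFrame:
    """Pearson r of each event's psi with a marker gene's expression.

    Returns one row per event with its consensus label and r (missing when
    psi or the marker is constant over the usable samples).
    """
    if marker_gene not in table.gene_expression.index:
        raise KeyError(f"marker gene {marker_gene!r} not in expression matrix")
    marker = table.gene_expression.loc[marker_gene].to_numpy(dtype=float)

    label_per_event = (
        classifications.groupby("event_id")["label"]
        .agg(_consensus_label)
        .rename("label")
    )
    rows = []
    for i, event_id in enumerate(table.psi.index):
        x = table.psi.iloc[i].to_numpy(dtype=float)
        mask = ~np.isnan(x)
        r = np.nan
        if mask.sum() >= 3:
            xm, mm = x[mask], marker[mask]
            if np.ptp(xm) > 0 and np.ptp(mm) > 0:
                r = float(stats.pearsonr(xm, mm).statistic)
        rows.append(
            {
                "event_id": event_id,
                "label": label_per_event.get(event_id, "UNCLASSIFIED"),
                "r": r,
            }
        )
    return pd.DataFrame(rows)


def _consensus_label(labels: pd.Series) -> str:
    for lab in ("UHP", "DHP", "TYPE0"):
        if (labels == lab).any():
            return lab
    return "UNCLASSIFIED"


@dataclass
class PoissonMixtureSplit:
    threshold: int
    assignments: np.ndarray  # True where the high-mean component dominates
    means: tuple[float, float]
    weights: tuple[float, float]
    converged: bool
    degenerate: bool


def split_by_poisson_mixture(
    counts,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> PoissonMixtureSplit:
    """Two-component Poisson mixture fitted by EM; integer split point.

    Component means start at the 25th/75th percentiles of the counts.
    The threshold is the smallest integer count whose posterior
    probability of the high-mean component exceeds 0.5.  If the
    components merge, a warning is raised and the threshold is set past
    the largest observed count.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("need a 1-D vector of at least 2 counts")
    if np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise ValueError("counts must be non-negative integers")

    lam = np.percentile(counts, [25.0, 75.0]).astype(float)
    if lam[0] == lam[1]:
        lam = np.array([lam[0] * 0.5 + 0.25, lam[1] * 1.5 + 0.75])
    lam = np.maximum(lam, 1e-6)
    w = np.array([0.5, 0.5])

    loglik_prev = -np.inf
    converged = False
    for _ in range(max_iter):
        logp = stats.poisson.logpmf(counts[:, None], lam[None, :]) + np.log(w)
        norm = np.logaddexp(logp[:, 0], logp[:, 1])
        resp = np.exp(logp - norm[:, None])
        loglik = float(norm.sum())
        w = resp.mean(axis=0)
        w = np.clip(w, 1e-12, None)
        lam = np.maximum(resp.T @ counts / (resp.sum(axis=0) * 1.0), 1e-9)
        if abs(loglik - loglik_prev) < tol:
            converged = True
            break
        loglik_prev = loglik

    lo, hi = (0, 1) if lam[0] <= lam[1] else (1, 0)
    degenerate = abs(lam[hi] - lam[lo]) < 1e-6
    if degenerate:
        warnings.warn(
            "Poisson mixture components merged; data look single-component",
            stacklevel=2,
        )
        threshold = int(counts.max()) + 1
        assignments = np.zeros(counts.size, dtype=bool)
    else:
        grid = np.arange(0, int(counts.max()) + 2)
        logp = stats.poisson.logpmf(grid[:, None], lam[None, :]) + np.log(w)
        post_hi = np.exp(
            logp[:, hi] - np.logaddexp(logp[:, 0], logp[:, 1])
        )
        above = np.nonzero(post_hi > 0.5)[0]
        threshold = int(grid[above[0]]) if above.size else int(counts.max()) + 1
        assignments = counts >= threshold
    return PoissonMixtureSplit(
        threshold=threshold,
        assignments=assignments,
        means=(float(lam[lo]), float(lam[hi])),
        weights=(float(w[lo]), float(w[hi])),
        converged=converged,
        degenerate=degenerate,
    )
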