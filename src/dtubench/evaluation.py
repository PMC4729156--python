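"""Performance evaluation: truth matching, TPR/FDR, stratification.

Gene-level results are matched against the simulation's truth table.
Feature identifiers that are not plain gene ids in the truth table
(notably '+'-joined gene complexes from aggregated flattening) cannot
be classified and are excluded from the confusion counts; truly
differential genes that received no q-value (filtered out, or hidden
inside a complex) are retained as uncalled and count as false negatives
at every threshold.  TPR is the fraction of truly differential genes
called at q <= threshold; FDR is the fraction of calls that are not
truly differential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.01, 0.05, 0.1)
DOMINANCE_BREAKS = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)
ISOFORM_BREAKS = (1, 2, 4, 8, np.inf)


@dataclass
class PerformanceRecord:
    arm: str
    stratum: str
    threshold: float
    TP: int
    FP: int
    TN: int
    FN: int
    n: int
    n_ds: int

    @property
    def TPR(self) -> float:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) else 0.0

    @property
    def FDR(self) -> float:
        return self.FP / (self.TP + self.FP) if (self.TP + self.FP) else 0.0

    def as_row(self) -> dict:
        return {
            "arm": self.arm,
            "stratum": self.stratum,
            "threshold": self.threshold,
            "TP": self.TP,
            "FP": self.FP,
            "TN": self.TN,
            "FN": self.FN,
            "TPR": self.TPR,
            "FDR": self.FDR,
            "n": self.n,
            "n_ds": self.n_ds,
            "fdr_controlled": self.FDR <= self.threshold,
        }


def match_truth(
    gene_results: pd.DataFrame,
    truth: pd.DataFrame,
    drop_uncalled_truth: bool = False,
) -> pd.DataFrame:
    """Label each result feature against the truth table.

    Returns one row per evaluable unit with columns feature_id, q_value
    (NaN for uncalled truth genes), truth_status in {dtu, non_dtu,
    unmatched}, and the truth's stratification variables.  With
    ``drop_uncalled_truth`` the truth genes absent from the results are
    dropped instead of retained as false negatives (the alternative,
    subset-style evaluation).
    """
    if gene_results["feature_id"].duplicated().any():
        raise ValueError("duplicate feature_ids in gene results")
    truth_idx = truth.set_index("gene_id")
    rows = []
    called = set()
    for _, r in gene_results.iterrows():
        fid = r["feature_id"]
        if fid in truth_idx.index:
            t = truth_idx.loc[fid]
            rows.append(
                dict(
                    feature_id=fid,
                    q_value=r["q_value"],
                    truth_status="dtu" if t["dtu_status"] else "non_dtu",
                    n_isoforms=t["n_isoforms"],
                    dominance_diff=t["dominance_diff"],
                    expected_count=t["expected_count"],
                )
            )
            called.add(fid)
        else:
            rows.append(
                dict(
                    feature_id=fid,
                    q_value=r["q_value"],
                    truth_status="unmatched",
                    n_isoforms=np.nan,
                    dominance_diff=np.nan,
                    expected_count=np.nan,
                )
            )
    if not drop_uncalled_truth:
        for gid, t in truth_idx.iterrows():
            if gid in called:
                continue
            rows.append(
                dict(
                    feature_id=gid,
                    q_value=np.nan,
                    truth_status="dtu" if t["dtu_status"] else "non_dtu",
                    n_isoforms=t["n_isoforms"],
                    dominance_diff=t["dominance_diff"],
                    expected_count=t["expected_count"],
                )
            )
    return pd.DataFrame(rows)


def confusion_at(
    labeled: pd.DataFrame, threshold: float, arm: str = "", stratum: str = "all"
) -> PerformanceRecord:
    """Tally TP/FP/TN/FN at q <= threshold over matched features."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    m = labeled[labeled["truth_status"] != "unmatched"]
    call = m["q_value"].notna() & (m["q_value"] <= threshold)
    is_dtu = m["truth_status"] == "dtu"
    TP = int((call & is_dtu).sum())
    FP = int((call & ~is_dtu).sum())
    FN = int((~call & is_dtu).sum())
    TN = int((~call & ~is_dtu).sum())
    return PerformanceRecord(
        arm=arm, stratum=stratum, threshold=threshold,
        TP=TP, FP=FP, TN=TN, FN=FN, n=len(m), n_ds=int(is_dtu.sum()),
    )


def stratify(
    labeled: pd.DataFrame, scheme: str, breaks=None
) -> pd.Series:
    """Assign each matched feature to a left-closed right-open stratum.

    Schemes: ``n_isoforms``, ``dominance``, ``expression``.  The top
    interval is closed; values outside the break range fall into the
    bottom/top stratum with a warning.
    """
    col = {
        "n_isoforms": "n_isoforms",
        "dominance": "dominance_diff",
        "expression": "expected_count",
    }[scheme]
    if breaks is None:
        breaks = {
            "n_isoforms": ISOFORM_BREAKS,
            "dominance": DOMINANCE_BREAKS,
        }.get(scheme)
        if breaks is None:
            v = labeled[col].dropna()
            breaks = tuple(np.quantile(v, [0, 1 / 3, 2 / 3, 1.0]))
    breaks = list(breaks)
    vals = labeled[col]
    out = pd.Series(index=labeled.index, dtype=object)
    labels = []
    for lo, hi in zip(breaks, breaks[1:]):
        top = hi == breaks[-1]
        labels.append(f"[{_fmt(lo)},{_fmt(hi)}{']' if top else ')'}")
    for idx, v in vals.items():
        if pd.isna(v):
            out[idx] = "unmatched"
            continue
        if v < breaks[0] or v > breaks[-1]:
            logger.warning("value %s outside break range for %s", v, scheme)
            out[idx] = labels[0] if v < breaks[0] else labels[-1]
            continue
        k = int(np.searchsorted(breaks, v, side="right")) - 1
        k = min(k, len(labels) - 1)
        out[idx] = labels[k]
    return out


def _fmt(x) -> str:
    if np.isinf(x):
        return "inf"
    if float(x).is_integer():
        return str(int(x))
    return f"{x:.3f}"


def stratified_performance(
    labeled: pd.DataFrame,
    arm: str,
    scheme: str | None = None,
    breaks=None,
    thresholds=DEFAULT_THRESHOLDS,
) -> list[PerformanceRecord]:
    """Confusion records per stratum (or 'all') and threshold."""
    records = []
    if scheme is None:
        for thr in thresholds:
            records.append(confusion_at(labeled, thr, arm=arm, stratum="all"))
        return records
    strata = stratify(labeled, scheme, breaks)
    for name in sorted(strata.dropna().unique()):
        if name == "unmatched":
            continue
        sub = labeled[strata == name]
        for thr in thresholds:
            records.append(confusion_at(sub, thr, arm=arm, stratum=name))
    return records


def compare_arms(
    arms: list[tuple[str, list[PerformanceRecord]]]
) -> pd.DataFrame:
    """Merge per-arm records into one long table.

    Arms must share strata and thresholds; each row carries TPR, FDR and
    the FDR-controlled flag (FDR <= threshold).
    """
    key_sets = []
    frames = []
    for label, records in arms:
        rows = [r.as_row() for r in records]
        for row in rows:
            row["arm"] = label
        frames.append(pd.DataFrame(rows))
        key_sets.append({(r["stratum"], r["threshold"]) for r in rows})
    if key_sets and any(k != key_sets[0] for k in key_sets):
        raise ValueError("arms have mismatched strata/threshold grids")
    return pd.concat(frames, ignore_index=True)


def plot_performance(table: pd.DataFrame, path=None):
    """FDR (x) vs TPR (y) scatter, one panel per stratum, vertical lines
    at each threshold; filled markers mark controlled FDR."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strata = sorted(table["stratum"].unique())
    fig, axes = plt.subplots(
        1, len(strata), figsize=(4 * len(strata), 4), squeeze=False
    )
    cmap = plt.get_cmap("tab10")
    arms = sorted(table["arm"].unique())
    for ax, stratum in zip(axes[0], strata):
        sub = table[table["stratum"] == stratum]
        for ci, arm in enumerate(arms):
            s = sub[sub["arm"] == arm].sort_values("threshold")
            filled = s["fdr_controlled"].to_numpy()
            ax.plot(s["FDR"], s["TPR"], "-", color=cmap(ci % 10), label=arm)
            ax.scatter(
                s["FDR"][filled], s["TPR"][filled],
                facecolor=cmap(ci % 10), edgecolor=cmap(ci % 10), zorder=3,
            )
            ax.scatter(
                s["FDR"][~filled], s["TPR"][~filled],
                facecolor="white", edgecolor=cmap(ci % 10), zorder=3,
            )
        for thr in sorted(sub["threshold"].unique()):
            ax.axvline(thr, color="grey", lw=0.5, ls=":")
        ax.set_xlabel("FDR")
        ax.set_ylabel("TPR")
        ax.set_title(stratum)
        ax.set_xlim(-0.02, 1)
        ax.set_ylim(-0.02, 1.02)
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
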