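"""Time-course expression stage: filter, contrasts, profiles, correlations.

Counts are transcripts x libraries; libraries belong to a 2-strain (E, Z)
by 3-timepoint (photophase, 1.3h, 4h) design with replicates (one group
may be short a replicate).  Inference is deliberately simple: log2 fold
changes of group mean CPM with a prior count, Welch t-tests on
log2(CPM + c) replicates, and Benjamini-Hochberg correction within each
contrast.  This preserves the contrast structure and FDR procedure of a
negative-binomial GLM analysis without reproducing one.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from allochrony.errors import ValidationError

__all__ = [
    "TIMEPOINTS",
    "CONTRASTS",
    "PROFILE_COLUMNS",
    "FilterResult",
    "read_counts",
    "read_metadata",
    "validate_counts",
    "cpm_normalize",
    "filter_weak",
    "contrast_table",
    "strain_timepoint_means",
    "profile_correlations",
    "correlation_pvalue",
    "cap_logfc",
    "plot_logfc_heatmap",
]

TIMEPOINTS = ("photophase", "1.3h", "4h")

#: contrast name -> (group A selector, group B selector); log_fc is
#: log2(A/B), so between-strain contrasts are positive when higher in E
#: and within-strain contrasts positive when higher at the earlier time.
CONTRASTS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "strain@photophase": (("E", "photophase"), ("Z", "photophase")),
    "strain@1.3h": (("E", "1.3h"), ("Z", "1.3h")),
    "strain@4h": (("E", "4h"), ("Z", "4h")),
    "E:photophase-vs-1.3h": (("E", "photophase"), ("E", "1.3h")),
    "E:photophase-vs-4h": (("E", "photophase"), ("E", "4h")),
    "E:1.3h-vs-4h": (("E", "1.3h"), ("E", "4h")),
    "Z:photophase-vs-1.3h": (("Z", "photophase"), ("Z", "1.3h")),
    "Z:photophase-vs-4h": (("Z", "photophase"), ("Z", "4h")),
    "Z:1.3h-vs-4h": (("Z", "1.3h"), ("Z", "4h")),
}

PROFILE_COLUMNS = tuple(f"{s}:{t}" for s in ("E", "Z") for t in TIMEPOINTS)


@dataclass(frozen=True)
class FilterResult:
    """Filtered count matrix plus the identity of dropped transcripts."""

    counts: pd.DataFrame
    kept: pd.Index
    dropped: pd.Index

    @property
    def log(self) -> dict:
        return {
            "n_input": len(self.kept) + len(self.dropped),
            "n_kept": len(self.kept),
            "n_dropped": len(self.dropped),
            "dropped": list(map(str, self.dropped)),
        }


def read_counts(path) -> pd.DataFrame:
    """Read a counts TSV (first column transcript id, then library columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_counts(df)
    return df


def read_metadata(path) -> pd.DataFrame:
    """Read library metadata CSV ``library_id,strain,timepoint,replicate``."""
    meta = pd.read_csv(path, dtype={"library_id": str, "replicate": int})
    required = {"library_id", "strain", "timepoint", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    bad_strain = set(meta["strain"]) - {"E", "Z"}
    if bad_strain:
        raise ValidationError(f"unknown strain labels: {sorted(bad_strain)}")
    bad_tp = set(meta["timepoint"]) - set(TIMEPOINTS)
    if bad_tp:
        raise ValidationError(f"unknown timepoints: {sorted(bad_tp)}")
    if meta.duplicated(["strain", "timepoint", "replicate"]).any():
        raise ValidationError("duplicate (strain, timepoint, replicate) in metadata")
    if meta["library_id"].duplicated().any():
        raise ValidationError("duplicate library_id in metadata")
    return meta.set_index("library_id")


def validate_counts(counts: pd.DataFrame) -> None:
    if (counts.to_numpy() < 0).any():
        raise ValidationError("count matrix contains negative entries")
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValidationError(
            f"libraries with zero total count: {list(map(str, zero.index))}"
        )


def _align_meta(counts: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    orphan_libs = counts.columns.difference(meta.index)
    orphan_meta = meta.index.difference(counts.columns)
    if len(orphan_libs) or len(orphan_meta):
        raise ValidationError(
            "metadata/matrix mismatch; libraries without metadata: "
            f"{list(map(str, orphan_libs))}; metadata without libraries: "
            f"{list(map(str, orphan_meta))}"
        )
    return meta.loc[counts.columns]


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: each column rescaled to sum to 1e6."""
    validate_counts(counts)
    return counts / counts.sum(axis=0) * 1e6


def filter_weak(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_libraries: int = 7
) -> FilterResult:
    """Drop transcripts lacking CPM >= ``min_cpm`` in >= ``min_libraries``.

    The default of 7 libraries is the size of the smallest two-group
    comparison in a 4+4 replicate design with one failed library.
    """
    if min_libraries > counts.shape[1]:
        raise ValidationError(
            f"min_libraries={min_libraries} exceeds the {counts.shape[1]} libraries"
        )
    cpm = cpm_normalize(counts)
    keep = (cpm >= min_cpm).sum(axis=1) >= min_libraries
    return FilterResult(
        counts=counts.loc[keep],
        kept=counts.index[keep],
        dropped=counts.index[~keep],
    )


def _group_columns(meta: pd.DataFrame, strain: str, timepoint: str) -> pd.Index:
    mask = (meta["strain"] == strain) & (meta["timepoint"] == timepoint)
    return meta.index[mask]


def contrast_table(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    prior_count: float = 0.5,
    min_group_size: int = 2,
) -> pd.DataFrame:
    """Log2 fold changes, p and BH q for the nine design contrasts.

    Per transcript and contrast: ``log_fc = log2((mean_cpm_A + c) /
    (mean_cpm_B + c))``; p from a Welch t-test on log2(CPM + c) replicate
    values; q by Benjamini-Hochberg within the contrast.  Transcripts with
    zero variance in both groups get p = 1 when the group means coincide
    and p = 0 otherwise.
    """
    meta = _align_meta(counts, meta)
    cpm = cpm_normalize(counts)
    logcpm = np.log2(cpm + prior_count)
    frames = []
    for name, ((sa, ta), (sb, tb)) in CONTRASTS.items():
        cols_a = _group_columns(meta, sa, ta)
        cols_b = _group_columns(meta, sb, tb)
        for label, cols in ((f"{sa} {ta}", cols_a), (f"{sb} {tb}", cols_b)):
            if len(cols) < min_group_size:
                raise ValidationError(
                    f"contrast {name!r}: group {label!r} has {len(cols)} "
                    f"libraries (< {min_group_size})"
                )
        a = logcpm[cols_a].to_numpy()
        b = logcpm[cols_b].to_numpy()
        log_fc = np.log2(
            (cpm[cols_a].mean(axis=1) + prior_count)
            / (cpm[cols_b].mean(axis=1) + prior_count)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # 0/0 for flat rows
            tstat, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        diff = a.mean(axis=1) - b.mean(axis=1)
        flat = np.isnan(p)
        p = np.where(flat, np.where(diff == 0.0, 1.0, 0.0), p)
        q = multipletests(p, method="fdr_bh")[1]
        frames.append(
            pd.DataFrame(
                {
                    "transcript": counts.index,
                    "contrast": name,
                    "log_fc": log_fc.to_numpy(),
                    "p_value": p,
                    "q_value": q,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def strain_timepoint_means(
    normalized: pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Mean normalized expression per (strain, timepoint) group.

    Returns transcripts x 6 columns in :data:`PROFILE_COLUMNS` order; a
    missing replicate simply averages over the libraries present.
    """
    meta = _align_meta(normalized, meta)
    out = {}
    for col in PROFILE_COLUMNS:
        strain, tp = col.split(":")
        libs = _group_columns(meta, strain, tp)
        if len(libs) == 0:
            raise ValidationError(f"no libraries for group {col!r}")
        out[col] = normalized[libs].mean(axis=1)
    return pd.DataFrame(out, index=normalized.index)


def correlation_pvalue(r: float, n_points: int = 6) -> float:
    """Two-sided p for a Pearson r over ``n_points`` paired values.

    Uses the t transform ``t = r * sqrt((n-2) / (1 - r^2))`` with n-2
    degrees of freedom.
    """
    if not (-1.0 <= r <= 1.0):
        raise ValidationError(f"correlation {r} outside [-1, 1]")
    df = n_points - 2
    if df < 1:
        raise ValidationError("need at least 3 points")
    if abs(r) >= 1.0:
        return float(np.nextafter(0.0, 1.0))  # keep p in (0, 1]
    t = abs(r) * np.sqrt(df / (1.0 - r * r))
    return float(max(2.0 * stats.t.sf(t, df), np.nextafter(0.0, 1.0)))


def profile_correlations(
    profiles: pd.DataFrame, alpha: float | None = None
) -> pd.DataFrame:
    """Pearson correlations between all unordered pairs of mean profiles.

    ``profiles`` is transcripts x 6 (see :func:`strain_timepoint_means`).
    Constant profiles are skipped with a warning.  When ``alpha`` is given
    only pairs with p < alpha are returned.
    """
    if profiles.shape[0] < 2:
        raise ValidationError("need at least two profiles")
    values = profiles.to_numpy(dtype=float)
    n_points = values.shape[1]
    sd = values.std(axis=1)
    constant = sd == 0.0
    if constant.any():
        warnings.warn(
            "skipping constant profiles: "
            f"{list(map(str, profiles.index[constant]))}",
            stacklevel=2,
        )
    usable = profiles.index[~constant]
    vals = values[~constant]
    if len(usable) < 2:
        raise ValidationError("fewer than two non-constant profiles")
    corr = np.corrcoef(vals)
    rows = []
    for i, j in itertools.combinations(range(len(usable)), 2):
        r = float(np.clip(corr[i, j], -1.0, 1.0))
        rows.append(
            {
                "transcript_a": usable[i],
                "transcript_b": usable[j],
                "r": r,
                "p_value": correlation_pvalue(r, n_points),
            }
        )
    out = pd.DataFrame(rows, columns=["transcript_a", "transcript_b", "r", "p_value"])
    if alpha is not None:
        out = out[out["p_value"] < alpha].reset_index(drop=True)
    return out


def cap_logfc(
    table: pd.DataFrame, lo: float = -2.0, hi: float = 2.0, q_cutoff: float = 0.05
) -> pd.DataFrame:
    """Clamp log_fc to [lo, hi] in a display copy; flag significance.

    Returns a copy of ``table`` with ``log_fc`` clipped and a boolean
    ``significant`` column (q < ``q_cutoff``) for asterisk markers.
    """
    if lo >= hi:
        raise ValidationError(f"cap bounds must satisfy lo < hi, got [{lo}, {hi}]")
    out = table.copy()
    out["log_fc"] = out["log_fc"].clip(lower=lo, upper=hi)
    out["significant"] = out["q_value"] < q_cutoff
    return out


def plot_logfc_heatmap(capped: pd.DataFrame, path, lo: float = -2.0, hi: float = 2.0):
    """Write a transcripts x contrasts heatmap of capped log fold changes.

    Significant cells are marked with an asterisk.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = capped.pivot(index="transcript", columns="contrast", values="log_fc")
    grid = grid[[c for c in CONTRASTS if c in grid.columns]]
    sig = (
        capped.pivot(index="transcript", columns="contrast", values="significant")
        .reindex(index=grid.index, columns=grid.columns)
        .fillna(False)
    )
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * grid.shape[1], 1.0 + 0.25 * max(grid.shape[0], 4))
    )
    im = ax.imshow(grid.to_numpy(), cmap="RdBu_r", vmin=lo, vmax=hi, aspect="auto")
    ax.set_xticks(range(grid.shape[1]), grid.columns, rotation=45, ha="right")
    ax.set_yticks(range(grid.shape[0]), grid.index, fontsize=6)
    for (i, j), is_sig in np.ndenumerate(sig.to_numpy()):
        if is_sig:
            ax.text(j, i, "*", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="log2 fold change (capped)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
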