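"""Per-cell mark derivations, normalizations and group classification.

Marks are the numeric values attached to each cell center: nuclear
intensity sum, concentration (sum / nuclear volume), apical area,
transcript-dot counts.  The central operation here is the per-sample
quantile classification that defines the signaling-low "center" group
used by the spatial statistics: because absolute intensity scales vary
between animals and staining runs, groups are always defined locally,
within each sample, never from a pooled threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cell_tables import CellTable

__all__ = [
    "GroupLabels",
    "MarkSummary",
    "concentration_from_sum",
    "zscore_marks",
    "classify_quantile_groups",
    "quantile_low_indices",
    "compare_variances",
    "correlate_marks",
    "neighbor_mark_stats",
    "population_dot_density",
    "mark_summary",
]


@dataclass(frozen=True)
class GroupLabels:
    """Per-cell low / intermediate / high labels for one mark channel.

    Per sample of size n, exactly ``floor(q_low * n)`` cells are labelled
    ``low`` and ``floor((1 - q_high) * n)`` labelled ``high``; the rest
    are ``intermediate``.
    """

    labels: pd.Series  # index-aligned with the source table's rows
    channel: str
    q_low: float
    q_high: float

    def mask(self, group: str) -> np.ndarray:
        return (self.labels == group).to_numpy()


@dataclass(frozen=True)
class MarkSummary:
    """Per-sample mean / SD / variance of one channel (population SD)."""

    sample_id: str
    channel: str
    mean: float
    sd: float
    variance: float
    n: int


def concentration_from_sum(total: float, volume: float) -> float:
    """Concentration mark: total intensity normalized by nuclear volume."""
    total = np.asarray(total, dtype=float)
    volume = np.asarray(volume, dtype=float)
    if np.any(volume <= 0):
        raise ValueError("nuclear volume must be > 0")
    out = total / volume
    return float(out) if out.ndim == 0 else out


def zscore_marks(
    table: CellTable,
    channel: str,
    scope: str = "per_sample",
    out_channel: str | None = None,
) -> CellTable:
    """Standard-score a channel: (value - population mean) / population SD.

    ``scope="per_sample"`` standardizes within each sample independently
    (the normalization used for inter-sample comparisons);
    ``scope="pooled"`` uses the grand mean/SD.  Raises if a scope unit is
    constant.
    """
    if scope not in {"per_sample", "pooled"}:
        raise ValueError(f"unknown scope: {scope!r}")
    df = table.data.copy()
    values = df[channel].to_numpy(dtype=float)
    out = np.empty_like(values)
    if scope == "pooled":
        groups = [np.arange(len(df))]
    else:
        groups = [
            np.flatnonzero((df["sample_id"] == sid).to_numpy())
            for sid in table.samples
        ]
    for idx in groups:
        v = values[idx]
        sd = v.std()  # population SD (ddof=0)
        if sd == 0:
            raise ValueError(f"constant channel {channel!r} within scope")
        out[idx] = (v - v.mean()) / sd
    name = out_channel or channel
    df[name] = out
    marks = table.mark_channels
    if name not in marks:
        marks = marks + (name,)
    return CellTable(
        df,
        mark_channels=marks,
        flag_channels=table.flag_channels,
        count_channels=table.count_channels,
    )


def quantile_low_indices(values: np.ndarray, q_low: float) -> np.ndarray:
    """Positions of the ``floor(q_low * n)`` smallest values.

    Rank-based with stable input-order tie-breaking, so the low-group
    size is a deterministic function of n alone — a property the
    permutation null relies on.
    """
    values = np.asarray(values, dtype=float)
    k = _floor_count(q_low, len(values))
    order = np.argsort(values, kind="stable")
    return order[:k]


def _floor_count(q: float, n: int) -> int:
    # floor(q*n) robust to binary representation (0.2*10 -> 2, not 1)
    return int(np.floor(q * n + 1e-9))


def classify_quantile_groups(
    table: CellTable,
    channel: str,
    q_low: float = 0.2,
    q_high: float = 0.8,
) -> GroupLabels:
    """Per-sample low / intermediate / high labels for a mark channel.

    Within each sample of size n the ``floor(q_low * n)`` cells of lowest
    mark are ``low`` and the ``floor((1 - q_high) * n)`` of highest mark
    are ``high`` (stable ties: for equal marks, earlier rows rank lower).
    Groups are defined per sample, never pooled, because mark scales vary
    between animals.
    """
    if not (0 < q_low < q_high < 1):
        raise ValueError("need 0 < q_low < q_high < 1")
    if channel not in table.mark_channels:
        raise KeyError(f"unknown mark channel: {channel!r}")
    df = table.data
    labels = pd.Series("intermediate", index=df.index, dtype=object)
    for sid in table.samples:
        idx = np.flatnonzero((df["sample_id"] == sid).to_numpy())
        if len(idx) == 0:
            raise ValueError(f"empty sample {sid!r}")
        v = df[channel].to_numpy(dtype=float)[idx]
        order = np.argsort(v, kind="stable")
        k_low = _floor_count(q_low, len(idx))
        k_high = _floor_count(1 - q_high, len(idx))
        labels.iloc[idx[order[:k_low]]] = "low"
        if k_high:
            labels.iloc[idx[order[-k_high:]]] = "high"
    return GroupLabels(labels=labels, channel=channel, q_low=q_low, q_high=q_high)


def compare_variances(
    values_a: np.ndarray,
    values_b: np.ndarray,
    method: str = "f",
) -> dict[str, float]:
    """Two-sided equality-of-variance comparison of two groups.

    Returns sample variances (ddof=1), their ratio var_a / var_b, and a
    two-sided p-value from the F-test (default) or the Brown-Forsythe
    Levene test (``method="levene"``).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    var_a = float(np.var(a, ddof=1))
    var_b = float(np.var(b, ddof=1))
    if method == "f":
        f = var_a / var_b
        dfa, dfb = len(a) - 1, len(b) - 1
        cdf = stats.f.cdf(f, dfa, dfb)
        p = float(2 * min(cdf, 1 - cdf))
        p = min(p, 1.0)
    elif method == "levene":
        p = float(stats.levene(a, b, center="median").pvalue)
    else:
        raise ValueError(f"unknown method: {method!r}")
    return {"var_a": var_a, "var_b": var_b, "ratio": var_a / var_b, "p": p}


def correlate_marks(
    values_a: np.ndarray, values_b: np.ndarray, method: str = "spearman"
) -> float:
    """Rank correlation (Spearman rho, average ranks for ties) of paired marks."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need paired values with n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant input")
    if method != "spearman":
        raise ValueError(f"unknown method: {method!r}")
    return float(stats.spearmanr(a, b).statistic)


def neighbor_mark_stats(
    table: CellTable,
    adjacency: pd.DataFrame,
    flag_channel: str,
) -> pd.DataFrame:
    """Per-cell neighbor counts over a physical-contact adjacency graph.

    ``adjacency`` is a per-sample undirected edge list with columns
    ``sample_id, cell_id_a, cell_id_b`` (cells sharing a membrane segment
    at their apicobasal interface, or a synthetic stand-in).  Returns one
    row per cell with ``n_neighbors`` and ``n_flagged_neighbors`` (number
    of neighbors positive for ``flag_channel``).
    """
    if flag_channel not in table.flag_channels:
        raise KeyError(f"unknown flag channel: {flag_channel!r}")
    df = table.data
    key = list(zip(df["sample_id"], df["cell_id"]))
    index = {k: i for i, k in enumerate(key)}
    flagged = df[flag_channel].to_numpy(dtype=bool)
    n_nb = np.zeros(len(df), dtype=int)
    n_fl = np.zeros(len(df), dtype=int)
    for row in adjacency.itertuples(index=False):
        ka = (str(row.sample_id), str(row.cell_id_a))
        kb = (str(row.sample_id), str(row.cell_id_b))
        if ka not in index or kb not in index:
            missing = ka if ka not in index else kb
            raise ValueError(f"adjacency references unknown cell: {missing}")
        ia, ib = index[ka], index[kb]
        n_nb[ia] += 1
        n_nb[ib] += 1
        n_fl[ia] += flagged[ib]
        n_fl[ib] += flagged[ia]
    return pd.DataFrame(
        {
            "sample_id": df["sample_id"],
            "cell_id": df["cell_id"],
            "n_neighbors": n_nb,
            "n_flagged_neighbors": n_fl,
        }
    )


def population_dot_density(total_dots: int, n_cells_with_area: int) -> float:
    """Field-level transcript density: total dots / cells with an apical area."""
    if n_cells_with_area <= 0:
        raise ValueError("need n_cells_with_area > 0")
    if total_dots < 0:
        raise ValueError("dot count must be >= 0")
    return total_dots / n_cells_with_area


def mark_summary(table: CellTable, channel: str) -> list[MarkSummary]:
    """Per-sample mean / population SD / variance of a channel."""
    out = []
    for sid in table.samples:
        v = table.marks(sid, channel)
        sd = float(v.std())
        out.append(
            MarkSummary(
                sample_id=sid,
                channel=channel,
                mean=float(v.mean()),
                sd=sd,
                variance=sd * sd,
                n=len(v),
            )
        )
    return out
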