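"""Mark-permutation null, deviation test and global envelope.

The null hypothesis is the absence of correlation between cell positions
and their marks: H0 : L_m = L_0.  A benchmark of this "uncorrelated"
model is built by fixing the positions and randomly permuting the marks
within each sample (random labelling); under H0 the observed pattern is
exchangeable with the permuted ones.  The reference curve L0_hat is the
pointwise average of ``n_ref`` (default 100) permutation replicates of
the pooled L_m curve.

The low-mark *center* cells are classified once, from the observed
marks, and held fixed across permutation replicates.  Three permutation
schemes are provided (``null_scheme``):

``"stratified"`` (default)
    Marks are exchanged within the center group and within the
    complement separately, so every replicate respects the observed
    constraint that the centers carry the lowest marks.  Conditionally
    on the group partition the within-stratum assignments are uniformly
    exchangeable under H0, making the p-value exactly valid; and
    because the pair geometry around the centers is common to the
    observed and all permuted curves, the null deviations isolate
    precisely the question of interest — whether the marks surrounding
    a low cell are arranged relative to it, rather than scattered at
    random.
``"full"``
    All marks exchanged over all positions, centers still fixed — the
    most literal transcription of exchanging "the marks of all points".
    Anticonservative at small radii: the observed pattern carries its
    lowest marks at the centers while replicates do not, a selection
    effect the stratified scheme removes.
``"recompute"``
    All marks exchanged and the low group re-derived from the permuted
    marks in each replicate.  Exactly exchangeable, but the spatial
    variability of random center subsets enters the null deviations
    and, at niche-scale cell counts, swamps mark-position correlations
    of any plausible effect size.

The deviation test then compares maximal deviations over radii [0, R]:

    u   = max_{r in [0, R]} |L_m_hat(r) - L0_hat(r)|
    u_i = max_{r in [0, R]} |L_i_hat(r) - L0_hat(r)|   (s fresh replicates)
    p_hat = 1 - (1 / (s + 1)) * sum_i 1(u_i < u)

With the default s = 99 the smallest attainable p_hat is 0.01.  The
global envelope D_max = max_i u_i localizes any rejection: radii where
the observed deviation curve L_m_hat - L0_hat exits the band
[-D_max, +D_max] are flagged, above meaning marks around a typical
center are higher than expected by chance, below meaning lower.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .cell_tables import CellTable, ObservationWindow, build_windows
from .lfunction import RadiusGrid, SamplePairCache
from .marks import quantile_low_indices

__all__ = [
    "NullEnsemble",
    "DeviationTestResult",
    "permute_marks",
    "estimate_null_reference",
    "deviation_statistic",
    "deviation_test",
    "global_envelope",
    "p_value_from_deviations",
    "PooledCurveEngine",
]


@dataclass(frozen=True)
class NullEnsemble:
    """Permutation replicates of the pooled L_m curve.

    ``reference_curve`` (L0_hat) averages ``n_ref`` replicates;
    ``replicate_curves`` holds the ``s`` test replicates whose deviations
    from L0_hat are ``deviations`` (u_i).
    """

    grid: RadiusGrid
    replicate_curves: np.ndarray  # (s, n_radii)
    reference_curve: np.ndarray  # (n_radii,)
    deviations: np.ndarray  # (s,)
    s: int
    n_ref: int
    seed: int


@dataclass(frozen=True)
class DeviationTestResult:
    """Observed deviation, Monte-Carlo p-value and global envelope."""

    u: float
    p_hat: float
    d_max: float
    exceed_hi: np.ndarray  # per-radius flags, deviation > +d_max
    exceed_lo: np.ndarray  # per-radius flags, deviation < -d_max
    R: float
    observed_curve: np.ndarray
    reference_curve: np.ndarray
    grid: RadiusGrid
    ensemble: NullEnsemble | None = field(default=None, repr=False)

    @property
    def deviation_curve(self) -> np.ndarray:
        return self.observed_curve - self.reference_curve


def permute_marks(
    table: CellTable, channel: str, seed: int | np.random.Generator
) -> CellTable:
    """Randomly exchange a channel's marks within each sample.

    Positions, every other channel and the per-sample multiset of values
    are untouched; only the assignment of marks to cells changes.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    df = table.data.copy()
    values = df[channel].to_numpy(dtype=float).copy()
    for sid in table.samples:
        idx = np.flatnonzero((df["sample_id"] == sid).to_numpy())
        values[idx] = values[idx][rng.permutation(len(idx))]
    df[channel] = values
    return table.copy_with(df)


def deviation_statistic(
    observed: np.ndarray,
    reference: np.ndarray,
    grid: RadiusGrid,
    R: float | None = None,
) -> float:
    """Maximal absolute deviation between two curves over radii [0, R]."""
    observed = np.asarray(observed, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if observed.shape != reference.shape or len(observed) != len(grid):
        raise ValueError("curves must share the radius grid")
    if R is None:
        R = grid.r_max
    mask = grid.r_values <= R
    return float(np.max(np.abs(observed - reference)[mask]))


def p_value_from_deviations(u: float, u_i: np.ndarray) -> float:
    """Monte-Carlo p-value: p_hat = 1 - (1/(s+1)) sum_i 1(u_i < u).

    Strict inequality, so ties between u and the u_i count toward a
    larger (conservative) p-value; the minimum attainable value is
    1 / (s + 1).
    """
    u_i = np.asarray(u_i, dtype=float)
    s = len(u_i)
    # integer-ratio form so that e.g. s = 99 with all u_i < u gives
    # exactly 0.01 rather than 1 - 0.99
    return float((s + 1 - int(np.sum(u_i < u))) / (s + 1))


class PooledCurveEngine:
    """Pooled low-group L_m curves over repeated mark permutations.

    Caches per-sample pair geometry once, then evaluates the observed
    curve and any number of permutation replicates cheaply.  The center
    group is the lowest ``q_low`` fraction per sample of the observed
    marks; how permuted curves treat it is set by ``null_scheme`` (see
    the module docstring).
    """

    def __init__(
        self,
        table: CellTable,
        channel: str,
        grid: RadiusGrid,
        windows: Mapping[str, ObservationWindow] | None = None,
        q_low: float = 0.2,
        weight: str | Callable = "mj",
        center_buffer: float = 0.0,
        null_scheme: str = "stratified",
    ) -> None:
        if null_scheme not in {"stratified", "full", "recompute"}:
            raise ValueError(f"unknown null scheme: {null_scheme!r}")
        if windows is None:
            windows = build_windows(table)
        self.grid = grid
        self.q_low = q_low
        self.weight = weight
        self.channel = channel
        self.null_scheme = null_scheme
        self.sample_ids = table.samples
        self._caches: list[SamplePairCache] = []
        self._marks: list[np.ndarray] = []
        self._eligible: list[np.ndarray] = []
        for sid in self.sample_ids:
            xy = table.positions(sid)
            win = windows[sid]
            self._caches.append(SamplePairCache(xy, grid, win))
            self._marks.append(table.marks(sid, channel))
            # optional inner buffer: only cells away from the window edge
            # may serve as centers; neighbors always come from all cells
            if center_buffer > 0:
                inner = (
                    (xy[:, 0] >= win.x_min + center_buffer)
                    & (xy[:, 0] <= win.x_max - center_buffer)
                    & (xy[:, 1] >= win.y_min + center_buffer)
                    & (xy[:, 1] <= win.y_max - center_buffer)
                )
                self._eligible.append(np.flatnonzero(inner))
            else:
                self._eligible.append(np.arange(len(xy)))
        # observed low group: centers used for every curve unless groups
        # are re-derived per permutation
        self._fixed_centers = [
            e[quantile_low_indices(m[e], q_low)]
            for m, e in zip(self._marks, self._eligible)
        ]
        self._complements = [
            np.setdiff1d(np.arange(len(m)), c)
            for m, c in zip(self._marks, self._fixed_centers)
        ]

    @property
    def n_total(self) -> int:
        return sum(c.n for c in self._caches)

    def pooled_curve(self, marks_per_sample: Sequence[np.ndarray]) -> np.ndarray:
        """Pooled L_m curve for given per-sample mark vectors."""
        curves = []
        for cache, marks, elig, fixed in zip(
            self._caches, marks_per_sample, self._eligible, self._fixed_centers
        ):
            if self.null_scheme == "recompute":
                centers = elig[quantile_low_indices(marks[elig], self.q_low)]
            else:
                centers = fixed
            curves.append(cache.l_curve(marks, centers, self.weight))
        return np.mean(curves, axis=0)

    def observed_curve(self) -> np.ndarray:
        return self.pooled_curve(self._marks)

    def n_centers(self) -> int:
        return sum(len(c) for c in self._fixed_centers)

    def permuted_curve(self, rng_streams: Sequence[np.random.Generator]) -> np.ndarray:
        """One permutation replicate (one independent stream per sample)."""
        permuted = []
        for k, (m, rng) in enumerate(zip(self._marks, rng_streams)):
            if self.null_scheme == "stratified":
                cen = self._fixed_centers[k]
                com = self._complements[k]
                mp = m.copy()
                mp[cen] = m[cen][rng.permutation(len(cen))]
                mp[com] = m[com][rng.permutation(len(com))]
            else:
                mp = m[rng.permutation(len(m))]
            permuted.append(mp)
        return self.pooled_curve(permuted)

    def _streams(self, seed: int, phase: int, rep: int) -> list[np.random.Generator]:
        # deterministic per (seed, phase, replicate, sample) stream
        return [
            np.random.default_rng([seed, phase, rep, k])
            for k in range(len(self.sample_ids))
        ]

    def replicate_block(self, seed: int, phase: int, count: int) -> np.ndarray:
        return np.array(
            [
                self.permuted_curve(self._streams(seed, phase, rep))
                for rep in range(count)
            ]
        )


def estimate_null_reference(
    table: CellTable,
    channel: str,
    grid: RadiusGrid,
    windows: Mapping[str, ObservationWindow] | None = None,
    q_low: float = 0.2,
    n_ref: int = 100,
    seed: int = 0,
    weight: str | Callable = "mj",
    null_scheme: str = "stratified",
) -> np.ndarray:
    """Reference curve L0_hat: average of ``n_ref`` permutation replicates."""
    if n_ref < 1:
        raise ValueError("need n_ref >= 1")
    engine = PooledCurveEngine(
        table, channel, grid, windows, q_low, weight,
        null_scheme=null_scheme,
    )
    block = engine.replicate_block(seed, phase=0, count=n_ref)
    return block.mean(axis=0)


def deviation_test(
    table: CellTable,
    channel: str,
    grid: RadiusGrid | None = None,
    windows: Mapping[str, ObservationWindow] | None = None,
    q_low: float = 0.2,
    s: int = 99,
    n_ref: int = 100,
    seed: int = 0,
    R: float | None = None,
    weight: str | Callable = "mj",
    reuse_reference: bool = False,
    null_scheme: str = "stratified",
    keep_curves: bool = True,
) -> DeviationTestResult:
    """Full mark-permutation deviation test with global envelope.

    Builds the reference curve from ``n_ref`` permutation replicates,
    draws ``s`` fresh replicates for the test set (or, with
    ``reuse_reference=True``, reuses the first ``s`` reference replicates
    for speed), and returns the observed deviation u, the Monte-Carlo
    p-value, and the +-D_max envelope with per-radius exceedance flags.
    """
    if s < 1:
        raise ValueError("need s >= 1")
    if grid is None:
        grid = RadiusGrid.regular()
    if R is None:
        R = grid.r_max
    if R > grid.r_max:
        raise ValueError("R exceeds the grid's largest radius")
    engine = PooledCurveEngine(
        table, channel, grid, windows, q_low, weight,
        null_scheme=null_scheme,
    )
    ref_block = engine.replicate_block(seed, phase=0, count=n_ref)
    reference = ref_block.mean(axis=0)
    if reuse_reference:
        if s > n_ref:
            raise ValueError("reuse_reference requires s <= n_ref")
        test_block = ref_block[:s]
    else:
        test_block = engine.replicate_block(seed, phase=1, count=s)
    observed = engine.observed_curve()
    u = deviation_statistic(observed, reference, grid, R)
    u_i = np.array(
        [deviation_statistic(c, reference, grid, R) for c in test_block]
    )
    p_hat = p_value_from_deviations(u, u_i)
    ensemble = NullEnsemble(
        grid=grid,
        replicate_curves=test_block if keep_curves else np.empty((0, len(grid))),
        reference_curve=reference,
        deviations=u_i,
        s=s,
        n_ref=n_ref,
        seed=seed,
    )
    return _envelope_result(observed, reference, grid, R, u, p_hat, ensemble)


def _envelope_result(
    observed: np.ndarray,
    reference: np.ndarray,
    grid: RadiusGrid,
    R: float,
    u: float,
    p_hat: float,
    ensemble: NullEnsemble,
) -> DeviationTestResult:
    d_max = float(np.max(ensemble.deviations))
    dev = observed - reference
    return DeviationTestResult(
        u=u,
        p_hat=p_hat,
        d_max=d_max,
        exceed_hi=dev > d_max,
        exceed_lo=dev < -d_max,
        R=R,
        observed_curve=observed,
        reference_curve=reference,
        grid=grid,
        ensemble=ensemble,
    )


def global_envelope(
    observed: np.ndarray, ensemble: NullEnsemble, R: float | None = None
) -> DeviationTestResult:
    """Envelope test of an observed curve against an existing ensemble.

    D_max is the largest replicate deviation; per-radius flags mark where
    the observed deviation curve exits [-D_max, +D_max].
    """
    if ensemble.s < 1 or len(ensemble.deviations) == 0:
        raise ValueError("empty ensemble")
    grid = ensemble.grid
    if R is None:
        R = grid.r_max
    u = deviation_statistic(observed, ensemble.reference_curve, grid, R)
    p_hat = p_value_from_deviations(u, ensemble.deviations)
    return _envelope_result(
        observed, ensemble.reference_curve, grid, R, u, p_hat, ensemble
    )
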