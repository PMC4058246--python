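"""Synthetic inputs with the statistical structure each pipeline stage assumes.

The original activity training set (20 compounds with measured pEC50) is not
public, and neither are the MD trajectories; every stage of the pipeline is
therefore exercised against generated stand-ins whose generating process is
known exactly:

* :func:`gen_qsar_table` — linear activity signal over planted descriptor
  columns among Gaussian distractors, with noise calibrated to the published
  training regime (n = 20, six descriptors, training R² ≈ 0.85),
* :func:`gen_trajectory` — a rigid scaffold with per-atom Gaussian jitter,
  optionally sampling around several reference conformations ("basins") for
  clustering tests,
* :func:`gen_hbond_distances` — a two-state Markov (telegraph) donor–acceptor
  distance series with a prescribed stationary contact fraction and dwell
  time, emulating the autocorrelated H-bond switching seen in real
  trajectories,
* :func:`fixture_library` — the shipped named small-molecule structures.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .molgraph import MolecularGraph, read_smiles_file
from .qsar import EQ1_COEFFICIENTS, EQ1_INTERCEPT, TrainingTable
from .trajstat import AtomRecord, Trajectory


def sigma_for_r2(beta: np.ndarray, target_r2: float,
                 n: int | None = None, k: int | None = None) -> float:
    """Noise σ giving a target R² for unit-variance regressors.

    With independent standard-normal columns the signal variance is Σβ², so
    the population R² is Σβ² / (Σβ² + σ²).  When ``n`` and ``k`` are given
    the target is read as a *training* R², which at small n is inflated over
    the population value; the usual degrees-of-freedom relation
    E[1 − R²_train] ≈ (1 − R²_pop)·(n − k − 1)/(n − 1) is inverted first.
    """
    signal_var = float(np.sum(np.asarray(beta, dtype=float) ** 2))
    if not 0 < target_r2 < 1:
        raise ValueError("target R² must lie in (0, 1)")
    r2_pop = target_r2
    if n is not None and k is not None:
        if n - k - 1 <= 0:
            raise ValueError("need n > k + 1 for the training-R² adjustment")
        r2_pop = 1.0 - (1.0 - target_r2) * (n - 1) / (n - k - 1)
        if r2_pop <= 0:
            raise ValueError("target training R² unreachable at this n, k")
    return float(np.sqrt(signal_var * (1.0 - r2_pop) / r2_pop))


_EQ1_BETA = np.array(list(EQ1_COEFFICIENTS.values()))


@dataclass
class QsarTableSpec:
    """Defaults emulate the published training regime: 20 compounds, the six
    model descriptors as informative columns, noise set for R² ≈ 0.85."""

    n: int = 20
    k_pool: int = 6
    planted: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    beta0: float = EQ1_INTERCEPT
    beta: tuple[float, ...] = tuple(_EQ1_BETA)
    sigma: float = sigma_for_r2(_EQ1_BETA, 0.85, n=20, k=6)
    block_correlation: float = 0.0  # equicorrelation among planted columns

    def __post_init__(self):
        if len(self.planted) != len(self.beta):
            raise ValueError("one β per planted column required")
        if max(self.planted, default=-1) >= self.k_pool:
            raise ValueError("planted indices must lie within the pool")
        if self.sigma < 0:
            raise ValueError("σ must be ≥ 0")
        if self.n <= len(self.planted) + 1:
            raise ValueError("need n > planted size + 1")


def gen_qsar_table(spec: QsarTableSpec, seed: int = 0) -> TrainingTable:
    """Synthetic training table: X ~ N(0,1), y = β0 + X[:, planted]·β + N(0,σ²)."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((spec.n, spec.k_pool))
    if spec.block_correlation > 0:
        rho = spec.block_correlation
        shared = rng.standard_normal((spec.n, 1))
        cols = list(spec.planted)
        x[:, cols] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * x[:, cols]
    y = spec.beta0 + x[:, list(spec.planted)] @ np.asarray(spec.beta)
    y = y + rng.normal(0.0, spec.sigma, size=spec.n)
    six = list(EQ1_COEFFICIENTS)
    names = []
    planted_set = dict(zip(spec.planted, range(len(spec.planted))))
    for idx in range(spec.k_pool):
        if idx in planted_set and planted_set[idx] < len(six):
            names.append(six[planted_set[idx]])
        else:
            names.append(f"X{idx:03d}")
    ids = [f"cpd{idx + 1:03d}" for idx in range(spec.n)]
    return TrainingTable(ids=ids, X=x, y=y, names=names)


@dataclass
class TrajectorySpec:
    """A jittering rigid scaffold; ``n_basins > 1`` samples around several
    well-separated reference conformations instead."""

    n_atoms: int = 20
    n_frames: int = 100
    jitter_sigma: float | tuple = 0.02  # nm, per axis; scalar or per-atom
    n_basins: int = 1
    basin_separation: float = 0.5  # nm scale of inter-basin deformation
    frames_per_basin: tuple[int, ...] = ()
    dt_ps: float = 10.0
    scaffold_extent: float = 1.0  # nm, size of the random scaffold cloud

    def __post_init__(self):
        sig = np.atleast_1d(np.asarray(self.jitter_sigma, dtype=float))
        if (sig < 0).any():
            raise ValueError("jitter σ must be ≥ 0")


def _default_atoms(n: int) -> list[AtomRecord]:
    return [
        AtomRecord(name="CA", resname="ALA", resid=i + 1, mass=12.011)
        for i in range(n)
    ]


def gen_trajectory(spec: TrajectorySpec, seed: int = 0) -> Trajectory:
    """Scaffold coordinates plus per-frame Gaussian jitter (nm).

    In basin mode the frames cycle through ``n_basins`` reference
    conformations (the scaffold plus a fixed large random deformation per
    basin), giving clearly separated conformational clusters with intra-basin
    spread set by ``jitter_sigma``.
    """
    rng = np.random.default_rng(seed)
    n, f = spec.n_atoms, spec.n_frames
    sigma = np.broadcast_to(
        np.atleast_1d(np.asarray(spec.jitter_sigma, dtype=float)), (n,)
    ).astype(float)
    scaffold = rng.uniform(0.0, spec.scaffold_extent, size=(n, 3))
    if spec.n_basins <= 1:
        refs = [scaffold]
        frame_basin = np.zeros(f, dtype=int)
    else:
        refs = [
            scaffold + rng.normal(0.0, spec.basin_separation / np.sqrt(3.0), size=(n, 3))
            for _ in range(spec.n_basins)
        ]
        if spec.frames_per_basin:
            if sum(spec.frames_per_basin) != f:
                raise ValueError("frames_per_basin must sum to n_frames")
            frame_basin = np.repeat(np.arange(spec.n_basins), spec.frames_per_basin)
        else:
            frame_basin = np.arange(f) % spec.n_basins
    coords = np.empty((f, n, 3))
    for t in range(f):
        jitter = rng.standard_normal((n, 3)) * sigma[:, None]
        coords[t] = refs[frame_basin[t]] + jitter
    times = np.arange(f, dtype=float) * spec.dt_ps
    return Trajectory(coordinates=coords, atoms=_default_atoms(n), times=times)


@dataclass
class HBondSeriesSpec:
    """Telegraph-process donor–acceptor distance series.

    The bound/unbound state is a two-state Markov chain with stationary
    bound fraction ``p`` and mean bound dwell time ``mean_dwell`` frames;
    the distance sits at ``level_in`` when bound and ``level_out`` when not,
    with a small Gaussian wobble.
    """

    p: float = 0.4
    n_frames: int = 10_000
    level_in: float = 0.25  # nm, below the 0.3 nm cutoff
    level_out: float = 0.45  # nm, above it
    mean_dwell: float = 50.0  # frames
    wobble: float = 0.005  # nm
    dt_ps: float = 4.0

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.level_in >= self.level_out:
            raise ValueError("bound level must be below unbound level")


def gen_hbond_distances(spec: HBondSeriesSpec, seed: int = 0) -> tuple[Trajectory, np.ndarray]:
    """Two-atom trajectory whose pair distance follows the telegraph series.

    Returns the trajectory (atom 0 fixed at the origin, atom 1 on the x-axis)
    and the generated distance series (nm).
    """
    rng = np.random.default_rng(seed)
    f = spec.n_frames
    if spec.p in (0.0, 1.0):
        state = np.full(f, bool(spec.p))
    else:
        # mean bound dwell = mean_dwell ⇒ leave-bound prob 1/mean_dwell;
        # stationarity fixes the unbound→bound rate at q10·p/(1−p)
        q10 = min(1.0 / spec.mean_dwell, 1.0)
        q01 = min(q10 * spec.p / (1.0 - spec.p), 1.0)
        state = np.empty(f, dtype=bool)
        state[0] = rng.random() < spec.p
        flips = rng.random(f)
        for t in range(1, f):
            if state[t - 1]:
                state[t] = flips[t] >= q10
            else:
                state[t] = flips[t] < q01
    levels = np.where(state, spec.level_in, spec.level_out)
    distances = levels + rng.normal(0.0, spec.wobble, size=f)
    distances = np.clip(distances, 0.01, None)
    coords = np.zeros((f, 2, 3))
    coords[:, 1, 0] = distances
    atoms = [
        AtomRecord(name="HZ3", resname="LYS", resid=367, mass=1.008),
        AtomRecord(name="O13", resname="LIG", resid=1, mass=15.999),
    ]
    times = np.arange(f, dtype=float) * spec.dt_ps
    return Trajectory(coordinates=coords, atoms=atoms, times=times), distances


@dataclass
class SynthSpec:
    """Bundle of stage specs, convenient for YAML-driven generation."""

    seed: int = 0
    qsar: QsarTableSpec = field(default_factory=QsarTableSpec)
    trajectory: TrajectorySpec = field(default_factory=TrajectorySpec)
    hbond: HBondSeriesSpec = field(default_factory=HBondSeriesSpec)


def fixture_library() -> list[MolecularGraph]:
    """The shipped named structures: screening candidates and the small
    oracle molecules used throughout the descriptor tests."""
    ref = resources.files("phytoscreen.data").joinpath("compounds.smi")
    with resources.as_file(ref) as path:
        return read_smiles_file(path)


def table1_inputs():
    """Published screening-results table shipped as input data.

    Returns a DataFrame with the dock scores and the externally predicted
    activities (MLR/SVM/BNT columns) for the candidate compounds and the
    control; these are injected inputs, not computed quantities.
    """
    import pandas as pd

    ref = resources.files("phytoscreen.data").joinpath("table1_screening.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
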