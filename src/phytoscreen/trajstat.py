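"""MD-trajectory post-analysis statistics.

Operates on a lightweight :class:`Trajectory` container (frames × atoms × 3
coordinates in nm, per-atom metadata, frame times in ps) and provides the
standard post-processing suite: Kabsch-superposed RMSD, radius of gyration,
per-atom RMSF over a window, hydrogen-bond occupancy under a distance
cutoff, GROMOS-style conformational clustering with a medoid representative,
signed torsion-angle series, and centered moving-average smoothing.

File input (multi-model PDB, XYZ with a CSV metadata sidecar) goes through
MDAnalysis; all statistics are computed here.  Units: nm for distances, ps
for times, degrees for angles, Da for masses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np


class TrajectoryError(ValueError):
    pass


@dataclass
class AtomRecord:
    name: str
    resname: str
    resid: int
    mass: float


@dataclass
class Trajectory:
    """F×N×3 coordinates (nm) with atom metadata and strictly increasing times (ps)."""

    coordinates: np.ndarray
    atoms: list[AtomRecord]
    times: np.ndarray

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryError("coordinates must have shape (frames, atoms, 3)")
        f, n, _ = self.coordinates.shape
        if len(self.atoms) != n:
            raise TrajectoryError("atom metadata must match coordinate atom count")
        if len(self.times) != f:
            raise TrajectoryError("one time per frame required")
        if f > 1 and not (np.diff(self.times) > 0).all():
            raise TrajectoryError("frame times must be strictly increasing")
        if not np.isfinite(self.coordinates).all():
            raise TrajectoryError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def select(self, expression: str | None) -> np.ndarray:
        """Indices matched by the selection mini-language.

        Clauses ``resid A-B`` / ``resid A,B,C``, ``name X,Y``,
        ``resname X,Y`` may be joined with ``and``. ``None`` or ``"all"``
        selects every atom.
        """
        if expression is None or expression.strip() in ("", "all"):
            return np.arange(self.n_atoms)
        mask = np.ones(self.n_atoms, dtype=bool)
        for clause in expression.split(" and "):
            parts = clause.strip().split(None, 1)
            if len(parts) != 2:
                raise TrajectoryError(f"cannot parse selection clause {clause!r}")
            key, arg = parts[0].lower(), parts[1]
            if key == "resid":
                wanted: set[int] = set()
                for token in arg.split(","):
                    token = token.strip()
                    if "-" in token:
                        lo, hi = token.split("-")
                        wanted.update(range(int(lo), int(hi) + 1))
                    else:
                        wanted.add(int(token))
                clause_mask = np.array([a.resid in wanted for a in self.atoms])
            elif key == "name":
                names = {t.strip() for t in arg.split(",")}
                clause_mask = np.array([a.name in names for a in self.atoms])
            elif key == "resname":
                names = {t.strip() for t in arg.split(",")}
                clause_mask = np.array([a.resname in names for a in self.atoms])
            else:
                raise TrajectoryError(f"unknown selection keyword {key!r}")
            mask &= clause_mask
        return np.flatnonzero(mask)


#: Masses for common elements, Da (fallback when a reader supplies none).
_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "Cl": 35.45, "Br": 79.904, "I": 126.904,
}

_ANGSTROM_TO_NM = 0.1


def _check_pdb_model_counts(path) -> None:
    """Cheap pre-scan: every MODEL block must have the same atom count."""
    counts, current, in_model, model_idx = [], 0, False, 0
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model, current = True, 0
                model_idx += 1
            elif rec in ("ATOM", "HETATM"):
                current += 1
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
    if in_model:
        counts.append(current)
    for idx, c in enumerate(counts):
        if c != counts[0]:
            raise TrajectoryError(
                f"atom count mismatch in {path}: model {idx + 1} has {c} atoms, "
                f"model 1 has {counts[0]}"
            )


def read_trajectory(path, fmt: str | None = None, sidecar=None, dt_ps: float = 1.0) -> Trajectory:
    """Read a multi-model PDB or an XYZ file (with CSV metadata sidecar).

    PDB coordinates (Å) are converted to nm.  XYZ files carry no residue or
    mass information, so a sidecar CSV with columns name,resname,resid,mass
    is required.  Frame times default to ``dt_ps``-spaced when the file
    carries none.
    """
    import MDAnalysis as mda

    path = str(path)
    fmt = (fmt or path.rsplit(".", 1)[-1]).lower()
    if fmt == "pdb":
        _check_pdb_model_counts(path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path)
        atoms = []
        for a in u.atoms:
            element = (a.element if hasattr(a, "element") and a.element
                       else "".join(c for c in a.name if c.isalpha())[:1].upper())
            mass = float(a.mass) if a.mass > 0 else _ELEMENT_MASSES.get(element, 0.0)
            atoms.append(AtomRecord(name=str(a.name), resname=str(a.resname),
                                    resid=int(a.resid), mass=mass))
    elif fmt == "xyz":
        if sidecar is None:
            raise TrajectoryError(f"XYZ input {path} requires a metadata sidecar "
                                  "(CSV with name,resname,resid,mass)")
        import pandas as pd

        meta = pd.read_csv(sidecar)
        missing = {"name", "resname", "resid", "mass"} - set(meta.columns)
        if missing:
            raise TrajectoryError(f"sidecar {sidecar} missing columns {sorted(missing)}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path)
        if len(meta) != len(u.atoms):
            raise TrajectoryError(
                f"sidecar {sidecar} has {len(meta)} atoms, {path} has {len(u.atoms)}")
        atoms = [AtomRecord(str(r["name"]), str(r["resname"]), int(r["resid"]),
                            float(r["mass"])) for _, r in meta.iterrows()]
    else:
        raise TrajectoryError(f"unsupported trajectory format {fmt!r}")

    frames, times = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            frames.append(u.atoms.positions.copy() * _ANGSTROM_TO_NM)
            times.append(ts.time)
    times = np.asarray(times, dtype=float)
    if len(times) > 1 and not (np.diff(times) > 0).all():
        times = np.arange(len(frames), dtype=float) * dt_ps
    return Trajectory(coordinates=np.array(frames), atoms=atoms, times=times)


def kabsch_rotation(p: np.ndarray, q: np.ndarray, weights=None) -> np.ndarray:
    """Optimal rotation aligning centered ``p`` onto centered ``q`` (Kabsch)."""
    w = np.ones(len(p)) if weights is None else np.asarray(weights, dtype=float)
    h = (p * w[:, None]).T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def rmsd_superpose(
    ref: np.ndarray,
    target: np.ndarray,
    selection: np.ndarray | None = None,
    masses: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Optimal rigid-body superposition of ``target`` onto ``ref``.

    The rotation is fit on ``selection`` (default: all atoms; at least three
    required) and applied to every atom; the returned RMSD is the
    (optionally mass-weighted) deviation over the selection.
    """
    ref = np.asarray(ref, dtype=float)
    target = np.asarray(target, dtype=float)
    sel = np.arange(len(ref)) if selection is None else np.asarray(selection)
    if len(sel) < 3:
        raise TrajectoryError("superposition needs ≥ 3 selected atoms")
    w = np.ones(len(sel)) if masses is None else np.asarray(masses, dtype=float)[sel]
    wsum = w.sum()
    ref_sel, tgt_sel = ref[sel], target[sel]
    ref_com = (ref_sel * w[:, None]).sum(axis=0) / wsum
    tgt_com = (tgt_sel * w[:, None]).sum(axis=0) / wsum
    rot = kabsch_rotation(tgt_sel - tgt_com, ref_sel - ref_com, w)
    superposed = (target - tgt_com) @ rot.T + ref_com
    diff = superposed[sel] - ref_sel
    rmsd = float(np.sqrt((w * (diff**2).sum(axis=1)).sum() / wsum))
    return rmsd, superposed


def rmsd_series(traj: Trajectory, selection: str | np.ndarray | None = None,
                ref_frame: int = 0, mass_weighted: bool = False) -> np.ndarray:
    """RMSD of every frame against a reference frame (default: the first)."""
    sel = traj.select(selection) if isinstance(selection, (str, type(None))) else np.asarray(selection)
    masses = traj.masses if mass_weighted else None
    ref = traj.coordinates[ref_frame]
    return np.array([
        rmsd_superpose(ref, frame, sel, masses)[0] for frame in traj.coordinates
    ])


def radius_of_gyration(frame: np.ndarray, masses: np.ndarray) -> float:
    """Rg = sqrt(Σ m_i ‖x_i − x_com‖² / Σ m_i), nm."""
    m = np.asarray(masses, dtype=float)
    if m.sum() <= 0:
        raise TrajectoryError("total mass must be positive")
    com = (frame * m[:, None]).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((frame - com) ** 2).sum(axis=1)).sum() / m.sum()))


def rg_series(traj: Trajectory, selection=None) -> np.ndarray:
    sel = traj.select(selection) if isinstance(selection, (str, type(None))) else np.asarray(selection)
    m = traj.masses[sel]
    return np.array([radius_of_gyration(f[sel], m) for f in traj.coordinates])


def _window_slice(traj: Trajectory, window) -> np.ndarray:
    if window is None:
        return np.arange(traj.n_frames)
    lo, hi = window
    idx = np.arange(traj.n_frames)[lo:hi]
    if len(idx) == 0:
        raise TrajectoryError(f"empty frame window {window}")
    return idx


def rmsf(traj: Trajectory, selection=None, window=None, fit: bool = True) -> np.ndarray:
    """Per-atom RMSF (nm) over a frame window.

    With ``fit=True`` (default) every frame is first superposed onto the
    window-average structure; the average is refined by a second
    superposition pass before fluctuations are measured.
    """
    sel = traj.select(selection) if isinstance(selection, (str, type(None))) else np.asarray(selection)
    frames_idx = _window_slice(traj, window)
    if len(frames_idx) < 2:
        raise TrajectoryError("RMSF needs at least 2 frames")
    coords = traj.coordinates[frames_idx][:, sel, :]
    if fit:
        ref = coords[0]
        for _ in range(2):  # two superposition passes to a refined mean
            aligned = np.array([rmsd_superpose(ref, f)[1] for f in coords])
            ref = aligned.mean(axis=0)
        coords = aligned
    mean = coords.mean(axis=0)
    return np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))


@dataclass(frozen=True)
class HBondSpec:
    """A named atom pair and a distance cutoff (nm) defining one H-bond."""

    atom_a: int
    atom_b: int
    cutoff: float = 0.30
    label: str = ""

    def __post_init__(self):
        if self.atom_a == self.atom_b:
            raise TrajectoryError("H-bond spec needs two distinct atoms")
        if self.cutoff < 0:
            raise TrajectoryError("cutoff must be non-negative")


@dataclass
class HBondResult:
    spec: HBondSpec
    occupancy_percent: float
    distances: np.ndarray


def hbond_occupancy(traj: Trajectory, specs: list[HBondSpec], window=None) -> list[HBondResult]:
    """Fraction of window frames with the pair distance below the cutoff.

    Reported as a percentage rounded to 2 decimal places; the full distance
    series is returned for plotting/export.
    """
    frames_idx = _window_slice(traj, window)
    out = []
    for spec in specs:
        d = np.linalg.norm(
            traj.coordinates[frames_idx, spec.atom_a, :]
            - traj.coordinates[frames_idx, spec.atom_b, :],
            axis=1,
        )
        occ = 100.0 * float((d < spec.cutoff).sum()) / len(frames_idx)
        out.append(HBondResult(spec=spec, occupancy_percent=round(occ, 2), distances=d))
    return out


@dataclass
class ClusterResult:
    assignment: np.ndarray  # cluster id per window frame, 0 = largest cluster
    clusters: list[list[int]]  # member frame indices, ordered by size
    representatives: list[int]  # medoid frame per cluster
    frame_indices: np.ndarray  # window frames the ids refer to (trajectory indexing)


def pairwise_rmsd_matrix(traj: Trajectory, selection=None, window=None,
                         mass_weighted: bool = False) -> tuple[np.ndarray, np.ndarray]:
    sel = traj.select(selection) if isinstance(selection, (str, type(None))) else np.asarray(selection)
    frames_idx = _window_slice(traj, window)
    coords = traj.coordinates[frames_idx][:, sel, :]
    masses = traj.masses[sel] if mass_weighted else None
    f = len(coords)
    m = np.zeros((f, f))
    for i in range(f):
        for j in range(i + 1, f):
            r, _ = rmsd_superpose(coords[i], coords[j], None, masses)
            m[i, j] = m[j, i] = r
    return m, frames_idx


def gromos_cluster(traj: Trajectory, selection=None, cutoff: float = 0.1,
                   window=None) -> ClusterResult:
    """GROMOS-style conformational clustering.

    Iteratively: the frame with the most neighbors within ``cutoff``
    (superposed RMSD) seeds a cluster together with those neighbors; the
    cluster is removed and the procedure repeats.  Each cluster's
    representative is its medoid — the member with the smallest summed RMSD
    to its co-members ("middle RMSD" structure).  Ties break toward the
    lowest frame index.
    """
    m, frames_idx = pairwise_rmsd_matrix(traj, selection, window)
    f = len(frames_idx)
    remaining = list(range(f))
    clusters: list[list[int]] = []
    while remaining:
        sub = m[np.ix_(remaining, remaining)]
        neighbor_counts = (sub <= cutoff).sum(axis=1)  # includes self
        leader_pos = int(np.argmax(neighbor_counts))  # argmax → lowest index on ties
        members = [remaining[k] for k in np.flatnonzero(sub[leader_pos] <= cutoff)]
        clusters.append(sorted(members))
        remaining = [k for k in remaining if k not in set(members)]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    assignment = np.empty(f, dtype=int)
    representatives = []
    for cid, members in enumerate(clusters):
        assignment[members] = cid
        if len(members) == 1:
            representatives.append(members[0])
        else:
            sub = m[np.ix_(members, members)]
            representatives.append(members[int(np.argmin(sub.sum(axis=1)))])
    return ClusterResult(assignment=assignment, clusters=clusters,
                         representatives=representatives, frame_indices=frames_idx)


def torsion_series(traj: Trajectory, indices: tuple[int, int, int, int]) -> np.ndarray:
    """Signed dihedral angle (degrees, (−180, 180]) per frame.

    Raw angles, no continuity unwrapping.  Colinear geometry yields NaN with
    a warning.
    """
    i, j, k, l = indices
    if len({i, j, k, l}) != 4:
        raise TrajectoryError("torsion needs four distinct atom indices")
    x = traj.coordinates
    b1 = x[:, j] - x[:, i]
    b2 = x[:, k] - x[:, j]
    b3 = x[:, l] - x[:, k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm1 = np.linalg.norm(n1, axis=1)
    norm2 = np.linalg.norm(n2, axis=1)
    degenerate = (norm1 < 1e-12) | (norm2 < 1e-12)
    if degenerate.any():
        warnings.warn(
            f"torsion {indices} undefined (colinear atoms) in "
            f"{int(degenerate.sum())} frame(s); NaN returned"
        )
    b2n = b2 / np.clip(np.linalg.norm(b2, axis=1), 1e-300, None)[:, None]
    yterm = (np.cross(n1, n2) * b2n).sum(axis=1)
    xterm = (n1 * n2).sum(axis=1)
    angles = np.degrees(np.arctan2(yterm, xterm))
    angles[angles <= -180.0] = 180.0  # fold −180 onto +180
    angles[degenerate] = np.nan
    return angles


def moving_average(series: np.ndarray, window: int = 21) -> np.ndarray:
    """Centered moving mean with edges truncated to the available frames."""
    series = np.asarray(series, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window > len(series):
        raise ValueError(f"window {window} exceeds series length {len(series)}")
    import pandas as pd

    return (
        pd.Series(series)
        .rolling(window=window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
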