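"""Post-hoc trajectory analytics: occupancy grids and binding-mode populations.

The occupancy grid records, per voxel of a regular lattice (default 0.5 A
spacing), the fraction of frames in which any real (non-ghost) probe site
lay within a capture radius (default 1.6 A) of the voxel center -- the
standard mixed-solvent hotspot map.  Binding modes are quantified two ways:
binning a signed dihedral angle, and distance-based clustering of the
ligand's pairwise-RMSD matrix with a principal-component projection for
plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "OccupancyGrid",
    "ModePopulations",
    "accumulate_grid",
    "contour_report",
    "dihedral_angle",
    "dihedral_populations",
    "rmsd_mode_clustering",
    "align_frames",
]


@dataclass
class OccupancyGrid:
    """Voxel occupancy field <O>_xyz = sum_i O^i_xyz / N_frames."""

    origin: np.ndarray
    spacing: float
    counts: np.ndarray  # integer per-voxel frame counts
    n_frames: int

    @property
    def occupancy(self) -> np.ndarray:
        return self.counts / self.n_frames

    def voxel_centers(self) -> np.ndarray:
        idx = np.indices(self.counts.shape).reshape(3, -1).T
        return self.origin + self.spacing * idx


@dataclass
class ModePopulations:
    """Frame counts and fractions per binding mode."""

    labels: np.ndarray
    mode_names: list
    counts: dict
    fractions: dict
    n_assigned: int
    n_skipped: int = 0
    projection: np.ndarray | None = None


def _probe_positions(frame, species: str | None):
    """Real-molecule site positions of one frame (Frame or bare array)."""
    if hasattr(frame, "ghost_flags"):
        pos = frame.positions
        keep = [
            i for i in range(len(frame.mol_species))
            if not frame.ghost_flags[i]
            and (species is None or frame.mol_species[i] == species)
        ]
        # toy frames are single-site; molecule i <-> site row i
        if pos.shape[0] == len(frame.mol_species):
            return pos[keep]
        raise NotImplementedError("multi-site frames need explicit site maps")
    return np.atleast_2d(np.asarray(frame, dtype=float))


def accumulate_grid(frames, spacing: float = 0.5, radius: float = 1.6,
                    species: str | None = None,
                    origin=None, shape=None, box=None) -> OccupancyGrid:
    """Binary per-frame voxel occupancy, averaged over frames.

    A voxel is occupied in a frame if any real probe site lies within
    ``radius`` of the voxel center; multiple nearby probes still count once
    (binary indicator).  The lattice is inferred from the frames' bounding
    box unless origin/shape are given.  Frames must be pre-aligned (toy
    systems have a fixed frame; see :func:`align_frames` otherwise).
    """
    frames = list(frames)
    if not frames:
        raise ValueError("empty trajectory")
    probe_sets = [_probe_positions(f, species) for f in frames]
    n_probes = sum(p.shape[0] for p in probe_sets)
    if origin is None or shape is None:
        occupied = [p for p in probe_sets if p.size]
        if not occupied:
            import warnings

            warnings.warn("no real probes in any frame; all-zero grid")
            origin = np.zeros(3)
            shape = (1, 1, 1)
        else:
            allpos = np.vstack(occupied)
            lo = allpos.min(axis=0) - radius - spacing
            hi = allpos.max(axis=0) + radius + spacing
            origin = lo
            shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing)) + 1
                          for i in range(3))
    origin = np.asarray(origin, dtype=float)
    counts = np.zeros(shape, dtype=np.int64)
    r_vox = int(np.ceil(radius / spacing))
    offsets = np.indices((2 * r_vox + 1,) * 3).reshape(3, -1).T - r_vox
    shape_arr = np.array(shape)
    for probes in probe_sets:
        if probes.size == 0:
            continue
        hit = np.zeros(shape, dtype=bool)
        for p in probes:
            base = np.floor((p - origin) / spacing).astype(int)
            vox = base[None, :] + offsets
            ok = np.all((vox >= 0) & (vox < shape_arr), axis=1)
            vox = vox[ok]
            centers = origin + spacing * vox
            d2 = np.sum((centers - p) ** 2, axis=1)
            close = vox[d2 <= radius**2]
            hit[close[:, 0], close[:, 1], close[:, 2]] = True
        counts += hit
    return OccupancyGrid(origin=origin, spacing=spacing, counts=counts,
                         n_frames=len(frames))


def contour_report(grid: OccupancyGrid, threshold: float):
    """Voxels with occupancy >= threshold, plus connected components.

    Returns (voxel index array, summary dict with component count and
    centroids in real coordinates).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    mask = grid.occupancy >= threshold
    labels, n_comp = ndimage.label(mask)
    centroids = []
    for c in range(1, n_comp + 1):
        idx = np.argwhere(labels == c)
        centroids.append(grid.origin + grid.spacing * idx.mean(axis=0))
    voxels = np.argwhere(mask)
    summary = {
        "n_voxels": int(mask.sum()),
        "n_components": int(n_comp),
        "centroids": centroids,
        "threshold": threshold,
    }
    return voxels, summary


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral in (-pi, pi] of four points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2)
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ b2n)
    ang = np.arctan2(y, x)
    return float(np.pi if ang <= -np.pi else ang)


def dihedral_populations(frames, site_refs, bin_edges,
                         species: str | None = None,
                         mode_names=None) -> ModePopulations:
    """Bin the per-frame signed dihedral into binding modes.

    ``site_refs`` is a sequence of four references: a fixed 3-vector
    (anchor point) or the string ``"molecule"`` for the tracked molecule's
    center.  Frames without a real molecule of the species are skipped and
    counted.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2:
        raise ValueError("need at least two bin edges")
    nbins = len(edges) - 1
    if mode_names is None:
        mode_names = list(range(nbins))
    labels = []
    skipped = 0
    for frame in frames:
        probes = _probe_positions(frame, species)
        if probes.shape[0] == 0:
            skipped += 1
            continue
        pts = []
        for ref in site_refs:
            if isinstance(ref, str) and ref == "molecule":
                pts.append(probes[0])
            else:
                pts.append(np.asarray(ref, dtype=float))
        ang = dihedral_angle(*pts)
        k = int(np.searchsorted(edges, ang, side="left")) - 1
        if 0 <= k < nbins:
            labels.append(k)
        else:
            skipped += 1
    labels = np.array(labels, dtype=int)
    counts = {mode_names[k]: int(np.sum(labels == k)) for k in range(nbins)}
    n = len(labels)
    fractions = {m: (c / n if n else 0.0) for m, c in counts.items()}
    return ModePopulations(labels=labels, mode_names=list(mode_names),
                           counts=counts, fractions=fractions,
                           n_assigned=n, n_skipped=skipped)


def rmsd_mode_clustering(frames, species: str | None = None,
                         n_modes: int = 2, linkage_method: str = "average",
                         ) -> ModePopulations:
    """Cluster bound frames by pairwise positional RMSD.

    No superposition is applied beyond any upstream alignment (toy frames
    share a fixed laboratory frame).  Hierarchical clustering (average
    linkage by default) on the condensed RMSD matrix is cut at ``n_modes``
    clusters; a 2-component PCA of the coordinates provides plotting
    coordinates.
    """
    coords = []
    for frame in frames:
        probes = _probe_positions(frame, species)
        if probes.shape[0] >= 1:
            coords.append(probes[0])
    if len(coords) < 2:
        raise ValueError("need at least 2 bound frames to cluster")
    if len(coords) < n_modes:
        raise ValueError("fewer bound frames than requested modes")
    X = np.asarray(coords)
    # pairwise RMSD of a single tracked site reduces to euclidean distance
    from scipy.spatial.distance import pdist

    dist = pdist(X)
    Z = linkage(dist, method=linkage_method)
    labels = fcluster(Z, t=n_modes, criterion="maxclust") - 1
    from sklearn.decomposition import PCA

    proj = PCA(n_components=2).fit_transform(X - X.mean(axis=0))
    counts = {int(k): int(np.sum(labels == k)) for k in np.unique(labels)}
    n = len(labels)
    fractions = {k: c / n for k, c in counts.items()}
    return ModePopulations(labels=labels, mode_names=sorted(counts),
                           counts=counts, fractions=fractions,
                           n_assigned=n, projection=proj)


def align_frames(frames_coords, reference: np.ndarray) -> list[np.ndarray]:
    """Rigid-body least-squares (Kabsch) alignment of coordinate frames.

    For externally supplied trajectories; toy-system frames are already in
    a fixed laboratory frame and do not need it.
    """
    ref = np.asarray(reference, dtype=float)
    ref_c = ref - ref.mean(axis=0)
    out = []
    for X in frames_coords:
        X = np.asarray(X, dtype=float)
        Xc = X - X.mean(axis=0)
        H = Xc.T @ ref_c
        U, _, Vt = np.linalg.svd(H)
        d = np.sign(np.linalg.det(Vt.T @ U.T))
        R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
        out.append(Xc @ R.T + ref.mean(axis=0))
    return out
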