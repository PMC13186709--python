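"""Bend-angle analysis of RNA stem loops from atomic coordinates.

The pipeline mirrors the helix-bend measurement used on the cryo-EM
models: obtain a helical trajectory for the stem loop (one point per
base-pair step), select the points belonging to the lower and upper
helices, fit each set with a best-fit 3D line by singular value
decomposition, and report the angle between the two principal axis
vectors (arccos of their dot product).  A simplified trajectory —
C1'-midpoints per base pair — replaces the external helicoidal-analysis
program; externally computed trajectories can be imported instead.

Also provides base-pair detection from coordinates and Kabsch rigid
superposition for stem-loop comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import Structure3D
from .secstruct import CANONICAL, PairTable

PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
PURINES = frozenset({"A", "G"})
PYRIMIDINES = frozenset({"C", "U"})

#: Hydrogen-bond donor/acceptor heavy atoms on each base.
POLAR_ATOMS = {
    "A": ("N1", "N3", "N6", "N7"),
    "G": ("N1", "N2", "N3", "O6", "N7"),
    "C": ("O2", "N3", "N4"),
    "U": ("O2", "N3", "O4"),
}

C1_C1_DIST = 10.4  # Å, pair C1'-C1' distance
C1_C1_TOL = 1.5
POLAR_CONTACT_MAX = 3.5  # Å, donor-acceptor heavy-atom cutoff
PLANE_ANGLE_MAX = 30.0  # degrees between base planes
MIN_SEQ_SEPARATION = 4  # enforce the minimum-loop pairing constraint


def _base_name(resname: str) -> Optional[str]:
    name = resname.strip().upper()
    if name in ("A", "C", "G", "U"):
        return name
    if len(name) == 2 and name[0] == "R" and name[1] in "ACGU":
        return name[1]
    return None


def _ring_atoms(base: str) -> tuple[str, ...]:
    return PURINE_RING if base in PURINES else PYRIMIDINE_RING


def _plane_normal(points: np.ndarray) -> np.ndarray:
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[-1]


def detect_base_pairs(structure: Structure3D, rna_chain: str) -> PairTable:
    """Detect base pairs geometrically within one RNA chain.

    A pair requires (i) C1'-C1' distance within 10.4 ± 1.5 Å, (ii) at
    least one inter-base donor-acceptor heavy-atom contact ≤ 3.5 Å and
    (iii) base planes within 30°.  Conflicts (a residue satisfying the
    criteria with several partners) are resolved greedily by a combined
    geometric score over all three criteria, keeping at most one
    partner per residue — the contact distance alone cannot separate a
    true pair from a cross-strand neighbour at a kinked junction, but
    the C1' distance and coplanarity terms can.  Residues
    with missing base atoms are skipped with a warning.  Pairs are
    classified canonical/noncanonical by residue identity.
    """
    if structure.chain_types.get(rna_chain) != "RNA":
        raise ValueError(f"chain {rna_chain!r} is not classified as RNA")
    residues = structure.residues(rna_chain)
    info: dict[int, dict] = {}
    for num, atoms in sorted(residues.items()):
        base = _base_name(next(iter(atoms.values())).resname)
        if base is None:
            continue
        ring_names = [n for n in _ring_atoms(base) if n in atoms]
        if "C1'" not in atoms and "C1*" not in atoms:
            warnings.warn(f"residue {num}: missing C1' atom, skipped")
            continue
        if len(ring_names) < 3:
            warnings.warn(f"residue {num}: missing base ring atoms, skipped")
            continue
        c1 = atoms.get("C1'", atoms.get("C1*"))
        ring = np.array([atoms[n].pos for n in ring_names])
        polar = {n: atoms[n].pos for n in POLAR_ATOMS[base] if n in atoms}
        if not polar:
            warnings.warn(f"residue {num}: no polar base atoms, skipped")
            continue
        info[num] = {
            "base": base,
            "c1": c1.pos,
            "normal": _plane_normal(ring),
            "polar": np.array(list(polar.values())),
        }
    if len(info) < 2:
        raise ValueError(f"chain {rna_chain!r} has fewer than 2 usable RNA residues")
    nums = sorted(info)
    candidates = []  # (combined geometric score, i, j)
    for ai, i in enumerate(nums):
        for j in nums[ai + 1 :]:
            if j - i < MIN_SEQ_SEPARATION:
                continue
            d = float(np.linalg.norm(info[i]["c1"] - info[j]["c1"]))
            if abs(d - C1_C1_DIST) > C1_C1_TOL:
                continue
            diff = info[i]["polar"][:, None, :] - info[j]["polar"][None, :, :]
            dmin = float(np.sqrt((diff**2).sum(axis=2)).min())
            if dmin > POLAR_CONTACT_MAX:
                continue
            cosang = abs(float(np.dot(info[i]["normal"], info[j]["normal"])))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle > PLANE_ANGLE_MAX:
                continue
            score = dmin + abs(d - C1_C1_DIST) + angle / PLANE_ANGLE_MAX
            candidates.append((score, i, j))
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in sorted(candidates):
        if i in used or j in used:
            continue
        used.update((i, j))
        pairs.append((i, j))
    n = max(nums)
    noncanonical = frozenset(
        (i, j) for i, j in pairs if (info[i]["base"], info[j]["base"]) not in CANONICAL
    )
    return PairTable(n=n, pairs=tuple(sorted(pairs)), noncanonical=noncanonical)


@dataclass(frozen=True)
class AxisTrajectory:
    """Ordered helical-axis points (Å), one per base-pair step, base -> loop."""

    points: np.ndarray
    source: str = "computed"  # or "imported"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise ValueError("trajectory needs >= 2 3D points")
        if self.source == "computed":
            spacing = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            if not ((spacing > 1.0) & (spacing < 6.0)).all():
                raise ValueError(
                    "computed trajectory spacing outside (1, 6) Å; broken stack?"
                )

    def __len__(self) -> int:
        return len(self.points)


def helical_trajectory(
    structure: Structure3D,
    pairs: Sequence[tuple[int, int]],
    rna_chain: Optional[str] = None,
) -> AxisTrajectory:
    """Simplified helical trajectory: the C1'-midpoint of each pair.

    Points are ordered base -> loop (ascending 5' position).  If missing
    atoms or non-physical spacing break the stack, the longest contiguous
    segment is kept; an error is raised if it has fewer than 4 points.
    """
    if rna_chain is None:
        chains = structure.rna_chains()
        if len(chains) != 1:
            raise ValueError("specify rna_chain: structure has %d RNA chains" % len(chains))
        rna_chain = chains[0]
    residues = structure.residues(rna_chain)
    mids: list[Optional[np.ndarray]] = []
    for i, j in sorted(pairs):
        a = residues.get(i, {}).get("C1'") or residues.get(i, {}).get("C1*")
        b = residues.get(j, {}).get("C1'") or residues.get(j, {}).get("C1*")
        if a is None or b is None:
            warnings.warn(f"pair ({i},{j}): missing C1' atoms; stack broken here")
            mids.append(None)
        else:
            mids.append((a.pos + b.pos) / 2.0)
    segments: list[list[np.ndarray]] = [[]]
    for m in mids:
        if m is None:
            segments.append([])
            continue
        if segments[-1] and not (1.0 < np.linalg.norm(m - segments[-1][-1]) < 6.0):
            segments.append([])
        segments[-1].append(m)
    longest = max(segments, key=len)
    if len(longest) < 4:
        raise ValueError(
            f"longest contiguous stack segment has {len(longest)} points (< 4)"
        )
    if len(longest) < sum(len(s) for s in segments):
        warnings.warn("broken stack: trajectory restricted to longest segment")
    return AxisTrajectory(points=np.array(longest), source="computed")


def load_trajectory(path: str | Path) -> AxisTrajectory:
    """Import an externally computed trajectory (TSV: index, x, y, z)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("index"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        rows.append((int(fields[0]), [float(v) for v in fields[1:4]]))
    rows.sort()
    return AxisTrajectory(points=np.array([xyz for _, xyz in rows]), source="imported")


@dataclass(frozen=True)
class LineFit:
    centroid: np.ndarray
    direction: np.ndarray  # unit vector
    rms_residual: float  # Å, perpendicular

    def __post_init__(self) -> None:
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.rms_residual < 0:
            raise ValueError("residual must be non-negative")


def fit_line_svd(points: np.ndarray) -> LineFit:
    """Best-fit 3D line through points by singular value decomposition.

    The direction is the principal right-singular vector of the centered
    coordinates, sign-oriented base -> loop (positive projection onto
    last - first point).  The residual is the root-mean-square
    perpendicular distance.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("need >= 2 3D points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if np.allclose(centered, 0.0):
        raise ValueError("degenerate fit: all points identical")
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    span = pts[-1] - pts[0]
    if np.dot(direction, span) < 0:
        direction = -direction
    perp_sq = (centered**2).sum(axis=1) - (centered @ direction) ** 2
    rms = float(np.sqrt(np.clip(perp_sq, 0.0, None).mean()))
    return LineFit(centroid=centroid, direction=direction, rms_residual=rms)


@dataclass(frozen=True)
class BendResult:
    angle_deg: float
    lower_fit: LineFit
    upper_fit: LineFit
    lower_range: tuple[int, int]
    upper_range: tuple[int, int]

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle_deg <= 180.0:
            raise ValueError("angle outside [0, 180]")

    def to_dict(self) -> dict:
        return {
            "angle_deg": self.angle_deg,
            "lower_range": list(self.lower_range),
            "upper_range": list(self.upper_range),
            "lower_fit": {
                "centroid": self.lower_fit.centroid.tolist(),
                "direction": self.lower_fit.direction.tolist(),
                "rms_residual": self.lower_fit.rms_residual,
            },
            "upper_fit": {
                "centroid": self.upper_fit.centroid.tolist(),
                "direction": self.upper_fit.direction.tolist(),
                "rms_residual": self.upper_fit.rms_residual,
            },
        }


def bend_angle(
    trajectory: AxisTrajectory,
    lower_range: tuple[int, int],
    upper_range: tuple[int, int],
) -> BendResult:
    """Inter-helix bend: angle between the two best-fit axis directions.

    Ranges are inclusive 0-based indices into the trajectory points and
    must be disjoint, each covering >= 2 points.  Before the dot
    product, both directions are oriented base -> loop along the vector
    between the two segment centroids — an orientation that does not
    depend on the order of points within a range, so a mirrored or
    re-sorted segment yields the same angle.
    """
    (l0, l1), (u0, u1) = lower_range, upper_range
    if l1 - l0 < 1 or u1 - u0 < 1:
        raise ValueError("each range must cover >= 2 points")
    if not (l1 < u0 or u1 < l0):
        raise ValueError(f"ranges {lower_range} and {upper_range} overlap")
    pts = trajectory.points
    if not (0 <= l0 and u1 < len(pts) and 0 <= u0 and l1 < len(pts)):
        raise ValueError("range outside trajectory")
    lower_fit = fit_line_svd(pts[l0 : l1 + 1])
    upper_fit = fit_line_svd(pts[u0 : u1 + 1])
    base_to_loop = upper_fit.centroid - lower_fit.centroid
    d_lower = lower_fit.direction * (1.0 if lower_fit.direction @ base_to_loop >= 0 else -1.0)
    d_upper = upper_fit.direction * (1.0 if upper_fit.direction @ base_to_loop >= 0 else -1.0)
    cosang = float(np.clip(np.dot(d_lower, d_upper), -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang)))
    return BendResult(
        angle_deg=angle,
        lower_fit=lower_fit,
        upper_fit=upper_fit,
        lower_range=lower_range,
        upper_range=upper_range,
    )


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``coords_b`` onto ``coords_a``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``coords_b @ rotation.T + translation`` best matches ``coords_a``;
    a proper rotation (det = +1) is enforced.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if len(a) < 3:
        raise ValueError("need >= 3 corresponding points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    if min(np.linalg.matrix_rank(a0), np.linalg.matrix_rank(b0)) < 2:
        warnings.warn("degenerate (rank < 2) point set; superposition ill-determined")
    h = b0.T @ a0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ca - rot @ cb
    moved = b @ rot.T + trans
    rmsd = float(np.sqrt(((moved - a) ** 2).sum(axis=1).mean()))
    return rot, trans, rmsd
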