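"""Ground-truth synthetic data for every analysis in the package.

Three generators: pseudo-atomic kinked A-form hairpins with a programmed
inter-helix bend (for the 3D bend pipeline), transcripts with implanted
stem-loop signal elements (for the scanner), and embryo-like images with
a known apical:basal intensity ratio (for localization quantification).
All generators are bit-reproducible under a fixed seed.

The helix generator uses textbook A-form step parameters (2.81 Å rise,
32.7° twist) and places per-nucleotide pseudo-atoms (C1', base ring,
Watson-Crick edge nitrogen) rather than full atomic detail: sufficient
for C1'-midpoint axis trajectories, geometric pair detection and
base-plane estimates.  C1' atoms of a pair are placed symmetrically
about the local helix axis, 10.4 Å apart, so that pair midpoints trace
the axis exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import Atom, IntensityImage, RnaSequence, Structure3D
from .secstruct import PairTable, build_pair_table

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

C1_RADIUS = 5.2  # Å from the helix axis; pair C1'-C1' distance = 10.4
RING_RADIUS = 1.4
EDGE_GAP = 2.9  # Å between the Watson-Crick edge atoms of a pair

_PURINE_RING6 = ("N1", "C2", "N3", "C4", "C5", "C6")  # N1 toward partner
_PYRIMIDINE_RING = ("N3", "C4", "C5", "C6", "N1", "C2")  # N3 toward partner


@dataclass(frozen=True)
class HelixSpec:
    """Two stacked ideal A-form duplex segments with a programmed kink."""

    n_bp_lower: int = 10
    n_bp_upper: int = 9
    kink_deg: float = 0.0
    rise_per_bp: float = 2.81  # Å, textbook A-form value
    twist_per_bp: float = 32.7  # degrees, textbook A-form value
    noise_sigma: float = 0.0  # Å, isotropic Gaussian per atom
    seed: int = 0
    n_bulge3: int = 2  # unpaired 3'-strand nucleotides at the junction
    loop_len: int = 4

    def __post_init__(self) -> None:
        if self.n_bp_lower < 2 or self.n_bp_upper < 2:
            raise ValueError("each segment needs >= 2 base pairs")
        if not 0.0 <= self.kink_deg <= 180.0:
            raise ValueError("kink_deg outside [0, 180]")
        if self.rise_per_bp <= 0 or self.twist_per_bp <= 0:
            raise ValueError("rise and twist must be positive")
        if self.loop_len < 3:
            raise ValueError("terminal loop needs >= 3 nucleotides")


#: exocyclic H-bonding atoms: (name, groove side) per base; +1 is the
#: side shared by both bases of a pair (so partners' atoms line up)
_EXOCYCLIC = {
    "A": (("N6", +1),),
    "G": (("O6", +1), ("N2", -1)),
    "C": (("N4", +1), ("O2", -1)),
    "U": (("O4", +1), ("O2", -1)),
}
_EXO_OFFSET = 1.2  # Å from the Watson-Crick edge atom, along the groove axis


def _base_atoms(
    base: str, c1: np.ndarray, u: np.ndarray, normal: np.ndarray, groove: np.ndarray
) -> list[tuple[str, np.ndarray]]:
    """Pseudo-atoms for one nucleotide.

    ``u`` is the in-plane unit vector from C1' toward the pairing
    partner (or outward for unpaired residues); ``normal`` is the base
    plane normal; ``groove`` picks a consistent groove side shared by
    both partners of a pair.  The ring is a planar polygon whose
    Watson-Crick edge nitrogen (N1 for purines, N3 for pyrimidines)
    sits on the chord at half the edge gap from the pair midpoint;
    exocyclic donors/acceptors flank it so each pair makes two to three
    polar contacts, as real Watson-Crick pairs do.
    """
    v = np.cross(normal, u)
    center = c1 + (C1_RADIUS - EDGE_GAP / 2.0 - RING_RADIUS) * u
    wc_edge = center + RING_RADIUS * u
    names = _PURINE_RING6 if base in "AG" else _PYRIMIDINE_RING
    atoms = [("C1'", c1)]
    for k, name in enumerate(names):
        a = np.radians(60.0 * k)
        atoms.append((name, center + RING_RADIUS * (np.cos(a) * u + np.sin(a) * v)))
    if base in "AG":
        # five-membered ring appendage on the C1' side of the hexagon
        for name, ang, rad in (("N9", 200.0, 1.9), ("C8", 240.0, 2.4), ("N7", 280.0, 2.0)):
            a = np.radians(ang)
            atoms.append((name, center + rad * (np.cos(a) * u + np.sin(a) * v)))
    for name, side in _EXOCYCLIC[base]:
        atoms.append((name, wc_edge + side * _EXO_OFFSET * groove))
    return atoms


def _rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def build_kinked_helix(spec: HelixSpec) -> tuple[Structure3D, dict]:
    """Generate a hairpin with two A-form segments bent by ``kink_deg``.

    The chain runs 5' lower strand, 5' upper strand, terminal loop,
    3' upper strand, 3'-strand junction bulge, 3' lower strand.  Returns
    the structure and a ground-truth dict with the programmed pairs,
    kink and trajectory index ranges of the two helices.
    """
    rng = np.random.default_rng(spec.seed)
    n1, n2, nb, nl = spec.n_bp_lower, spec.n_bp_upper, spec.n_bulge3, spec.loop_len
    total = 2 * (n1 + n2) + nb + nl
    # sequence: random 5' strand and loop/bulge, complementary 3' strand
    seq = [""] * (total + 1)  # 1-based
    pairs: list[tuple[int, int]] = []
    for p in range(n1):
        pairs.append((p + 1, total - p))
    for q in range(n2):
        pairs.append((n1 + q + 1, n1 + n2 + nl + (n2 - q)))
    for i, j in pairs:
        b = rng.choice(list("ACGU"))
        seq[i], seq[j] = b, _COMPLEMENT[b]
    loop_positions = list(range(n1 + n2 + 1, n1 + n2 + nl + 1))
    bulge_positions = list(range(n1 + 2 * n2 + nl + 1, n1 + 2 * n2 + nl + nb + 1))
    for p in loop_positions + bulge_positions:
        seq[p] = rng.choice(list("ACGU"))

    twist = np.radians(spec.twist_per_bp)
    rise = spec.rise_per_bp
    rot = _rot_x(spec.kink_deg)
    top = np.array([0.0, 0.0, (n1 - 1) * rise])  # axis point of last lower pair

    def axis_point(step: int) -> np.ndarray:
        """Axis point of pair index ``step`` (0-based over the full stack)."""
        if step < n1:
            return np.array([0.0, 0.0, step * rise])
        return top + rot @ np.array([0.0, 0.0, (step - n1 + 1) * rise])

    def pair_c1(step: int, strand: int) -> np.ndarray:
        """C1' position for one strand of pair ``step`` (strand 0 = 5')."""
        theta = step * twist + (np.pi if strand else 0.0)
        radial = np.array([np.cos(theta), np.sin(theta), 0.0]) * C1_RADIUS
        if step >= n1:
            radial = rot @ radial
        return axis_point(step) + radial

    def local_axis(step: int) -> np.ndarray:
        z = np.array([0.0, 0.0, 1.0])
        return rot @ z if step >= n1 else z

    atoms: list[Atom] = []

    def add_residue(
        resnum: int, c1: np.ndarray, u: np.ndarray, normal: np.ndarray,
        groove: Optional[np.ndarray] = None,
    ) -> None:
        base = seq[resnum]
        g = np.cross(normal, u) if groove is None else groove
        for name, pos in _base_atoms(base, c1, u, normal, g):
            p = pos + rng.normal(0.0, spec.noise_sigma, 3) if spec.noise_sigma else pos
            atoms.append(Atom("A", resnum, base, name, *p))

    step_of: dict[int, tuple[int, int]] = {}
    for k, (i, j) in enumerate(pairs):
        step = i - 1  # pairs are stacked in 5'-position order
        step_of[i] = (step, 0)
        step_of[j] = (step, 1)
    for resnum in range(1, total + 1):
        if resnum in step_of:
            step, strand = step_of[resnum]
            c1 = pair_c1(step, strand)
            mid = axis_point(step)
            u = (mid - c1) / np.linalg.norm(mid - c1)
            ax = local_axis(step)
            # groove side defined from the 5' strand so both partners agree
            groove = np.cross(ax, u if strand == 0 else -u)
            add_residue(resnum, c1, u, ax, groove)
        elif resnum in loop_positions:
            k = resnum - loop_positions[0]
            ax = local_axis(n1 + n2 - 1)
            base_pt = axis_point(n1 + n2 - 1) + (k + 1) * rise * ax
            theta = (n1 + n2 + k) * twist
            radial = rot @ (np.array([np.cos(theta), np.sin(theta), 0.0]) * 3.0)
            c1 = base_pt + radial
            # edge points outward so loop residues never satisfy pairing
            add_residue(resnum, c1, radial / np.linalg.norm(radial), ax)
        else:  # 3'-strand junction bulge, pushed away from the stem
            k = resnum - bulge_positions[0]
            theta = np.pi + (n1 + k) * twist
            radial = np.array([np.cos(theta), np.sin(theta), 0.0]) * 9.0
            c1 = top + 0.5 * rise * np.array([0.0, 0.0, 1.0]) + radial
            u = radial / np.linalg.norm(radial)
            add_residue(resnum, c1, u, np.array([0.0, 0.0, 1.0]))

    structure = Structure3D(atoms=atoms, chain_types={"A": "RNA"})
    truth = {
        "pairs": sorted(pairs),
        "kink_deg": spec.kink_deg,
        "sequence": "".join(seq[1:]),
        "lower_traj_range": (0, n1 - 1),
        "upper_traj_range": (n1, n1 + n2 - 1),
        "loop": loop_positions,
        "bulge3": bulge_positions,
    }
    return structure, truth


def _hairpin_from_plan(
    n: int,
    pairs: list[tuple[int, int]],
    site_bases: dict[int, str],
    loop_bases: str,
    loop_start: int,
) -> tuple[str, str]:
    """Assemble (sequence, dot-bracket) from a pairing plan.

    Paired positions default to an alternating G/C register on the 5'
    strand with Watson-Crick partners; ``site_bases`` overrides 5'-side
    identities (partners follow by complement); unpaired non-loop
    positions are A.
    """
    seq = ["A"] * (n + 1)
    db = ["."] * (n + 1)
    for k, (i, j) in enumerate(sorted(pairs)):
        five = site_bases.get(i, "GC"[k % 2])
        seq[i], seq[j] = five, _COMPLEMENT[five]
        db[i], db[j] = "(", ")"
    for k, b in enumerate(loop_bases):
        seq[loop_start + k] = b
    return "".join(seq[1:]), "".join(db[1:])


def tls_like_element() -> tuple[str, str]:
    """A synthetic 44-nt primary-signal hairpin.

    Constructed (not a natural sequence) to carry every hallmark of the
    reference transport-and-localization signal: an 8-bp lower helix, a
    short internal helix flanked by two 3'-strand bulges, a 9-bp upper
    helix, a 4-nt loop, U-A pairs at positions 6-39 and 15-28 (the ED1
    and ED2 sites, 8 bp apart on a contiguous 5' strand) and the
    stacked U7-A38 neighbour.
    """
    pairs = (
        [(p, 45 - p) for p in range(1, 9)]  # lower helix, bulge at 36
        + [(9, 35), (10, 34)]  # short internal helix, bulge at 33
        + [(11 + k, 32 - k) for k in range(9)]  # upper helix, closes (19, 24)
    )
    sites = {6: "U", 7: "U", 15: "U", 16: "A"}
    return _hairpin_from_plan(44, pairs, sites, "UUCG", 20)


def support_element() -> tuple[str, str]:
    """A synthetic straight-stem support element (34 nt).

    Carries correctly spaced U-A pairs at both ED sites but no 3'-strand
    bulge and no distinct upper helix, so it scores as a support-tier
    element (engages the ED sites only, like a low-affinity second stem
    loop), not as a primary signal.
    """
    pairs = [(k, 35 - k) for k in range(1, 16)]
    sites = {2: "U", 11: "U"}
    return _hairpin_from_plan(34, pairs, sites, "GAAA", 16)


def gc_mutant_element() -> tuple[str, str]:
    """The primary-signal hairpin with both ED-site U-A pairs mutated to G-C."""
    seq, db = tls_like_element()
    s = list(seq)
    for five, three in ((6, 39), (15, 28)):
        s[five - 1], s[three - 1] = "G", "C"
    return "".join(s), db


@dataclass(frozen=True)
class SignalDef:
    name: str
    sequence: str
    dotbracket: str
    position: int  # 1-based start in the final transcript
    tier: str  # expected scanner tier


@dataclass(frozen=True)
class ImplantSpec:
    background_length: int = 1500
    signals: tuple[SignalDef, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        spans = []
        for s in self.signals:
            if len(s.sequence) != len(s.dotbracket):
                raise ValueError(f"signal {s.name!r}: sequence/structure length mismatch")
            lo, hi = s.position, s.position + len(s.sequence) - 1
            if lo < 1 or hi > self.background_length:
                raise ValueError(f"signal {s.name!r} at {lo}..{hi} outside transcript")
            spans.append((lo, hi, s.name))
        spans.sort()
        for (l1, h1, n1), (l2, h2, n2) in zip(spans, spans[1:]):
            if l2 <= h1:
                raise ValueError(f"signals {n1!r} and {n2!r} overlap")


def implant_signals(spec: ImplantSpec) -> tuple[RnaSequence, PairTable, list[dict]]:
    """Random background transcript with signal elements spliced in.

    Background is uniform ACGU and unpaired in the composite structure;
    each signal replaces the background segment starting at its target
    position.  Returns the sequence, composite pair table and a truth
    table of spans and expected tiers.
    """
    rng = np.random.default_rng(spec.seed)
    seq = list(rng.choice(list("ACGU"), size=spec.background_length))
    db = ["."] * spec.background_length
    truth = []
    for s in spec.signals:
        lo = s.position - 1
        seq[lo : lo + len(s.sequence)] = list(s.sequence)
        db[lo : lo + len(s.sequence)] = list(s.dotbracket)
        truth.append(
            {"name": s.name, "start": s.position, "end": s.position + len(s.sequence) - 1, "tier": s.tier}
        )
    rna = RnaSequence(id=f"synthetic_{spec.seed}", residues="".join(seq))
    return rna, build_pair_table(rna, "".join(db)), truth


def synth_embryo_image(
    ratio: float,
    shape: tuple[int, int] = (256, 256),
    pixel_size: float = 0.21,
    background: float = 100.0,
    basal_amp: float = 50.0,
    roi_area_um2: float = 7.391,
    n_puncta: int = 4,
    noise: bool = True,
    seed: int = 0,
) -> tuple[IntensityImage, dict]:
    """Embryo-like image: plateau + basal signal band + apical puncta.

    Apical puncta are flat discs of one ROI area whose amplitude above
    background is ``ratio`` times the basal band amplitude, so the
    background-corrected apical:basal intensity ratio of the image is
    ``ratio`` by construction.  Poisson noise is applied per pixel when
    ``noise`` is set.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    h, w = shape
    img = np.full(shape, float(background))
    basal_rows = (int(0.30 * h), int(0.55 * h))
    img[basal_rows[0] : basal_rows[1], :] += basal_amp
    radius_px = np.sqrt(roi_area_um2 / np.pi) / pixel_size
    punctum_row = int(0.08 * h)
    centers = []
    rr, cc = np.mgrid[0:h, 0:w]
    for k in range(n_puncta):
        col = (k + 1) * w // (n_puncta + 1)
        centers.append((punctum_row, col))
        mask = (rr - punctum_row) ** 2 + (cc - col) ** 2 <= radius_px**2
        img[mask] += ratio * basal_amp
    if noise:
        rng = np.random.default_rng(seed)
        img = rng.poisson(img).astype(float)
    truth = {
        "ratio": ratio,
        "centers": centers,
        "background": background,
        "basal_amp": basal_amp,
        "basal_rows": basal_rows,
        "radius_px": radius_px,
    }
    return IntensityImage(pixels=img, pixel_size=pixel_size), truth
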