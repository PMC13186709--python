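"""Score stem loops and transcripts against the Egl recognition rules.

A competent localization signal is a bent stem loop with upper and lower
helices of at least 6 bp separated by a short segment carrying 3'-strand
bulges, plus favourable base-pair identities at two minor-groove sites
(the ED1 and ED2 interaction sites) separated by 8 bp.  Transcripts are
selected by coincidence: at least one primary signal plus a second
primary-or-support element on the same RNA.

Base-pair preference at the ED sites follows the empirical rank order
U-A > C-G > A-U > G-C (a 5'-pyrimidine / 3'-purine bias on top of steric
exclusion of guanine), with the noncanonical C-U pair tolerated at ED1
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .io import RnaSequence
from .secstruct import (
    NotSimpleStemLoopError,
    PairTable,
    StemLoopAnnotation,
    annotate_stemloop,
    hairpin_spans,
)

ED1 = "ED1"
ED2 = "ED2"

#: Ordinal preference weights for 5'->3' base-pair identities at the ED
#: sites.  Rank order is empirical: U-A > C-G > A-U > G-C.
DEFAULT_WEIGHTS: dict[tuple[str, str], int] = {
    ("U", "A"): 3,
    ("C", "G"): 2,
    ("A", "U"): 1,
    ("G", "C"): 0,
}
#: The noncanonical C-U pair is tolerated at ED1 (no bulky purine to
#: clash with the recognition surface) but not at ED2.
CU_ED1_WEIGHT = 2


class SitesUnassignableError(ValueError):
    """Raised when a stack is too short (or 5'-interrupted) for both sites."""


@dataclass(frozen=True)
class ScanConfig:
    spacing: int = 8  # base pairs strictly between ED1 and ED2
    ed2_offset_from_loop: int = 5  # closing pair counts as 1
    offset_window: int = 2  # scan ed2 offsets default +/- window
    min_helix_bp: int = 6
    geometry_bonus: int = 1  # score bonus per satisfied rule flag
    weights: dict[tuple[str, str], int] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))

    def __post_init__(self) -> None:
        w = self.weights
        if not (w[("U", "A")] > w[("C", "G")] > w[("A", "U")] > w[("G", "C")]):
            raise ValueError("weights must preserve the rank order U-A > C-G > A-U > G-C")


@dataclass(frozen=True)
class SiteAssignment:
    ed1_pair: tuple[int, int]
    ed1_bases: tuple[str, str]
    ed2_pair: tuple[int, int]
    ed2_bases: tuple[str, str]
    spacing_bp: int
    ed2_offset_from_loop: int
    #: the pair stacked directly on the loop side of ED1 (the second
    #: ED1-adjacent position, e.g. U7-A38); reported informationally
    ed1_neighbor_pair: Optional[tuple[int, int]] = None


def score_ed_pair(
    base5: str,
    base3: str,
    site: str,
    weights: Optional[dict[tuple[str, str], int]] = None,
) -> int:
    """Ordinal preference score for the 5'/3' bases of an ED-site pair."""
    if base5 not in "ACGU" or base3 not in "ACGU":
        raise ValueError(f"invalid base symbol in ({base5!r}, {base3!r})")
    if site not in (ED1, ED2):
        raise ValueError(f"site must be {ED1!r} or {ED2!r}, got {site!r}")
    w = DEFAULT_WEIGHTS if weights is None else weights
    if (base5, base3) == ("C", "U"):
        return CU_ED1_WEIGHT if site == ED1 else 0
    return w.get((base5, base3), 0)


def assign_ed_sites(
    annotation: StemLoopAnnotation,
    ed2_offset_from_loop: int = 5,
    spacing: int = 8,
) -> SiteAssignment:
    """Place the ED2 and ED1 sites on a stem-loop stack.

    ED2 sits at ``ed2_offset_from_loop`` pairs from the closing pair
    (closing pair = 1), its distance from the loop being fixed by the
    XAD-ED2 interaction.  ED1 lies ``spacing`` pairs further toward the
    helix base, counted along the 5'-strand stack: 3'-strand bulges do
    not interrupt the count, but a 5'-strand discontinuity does.
    """
    stack = annotation.stack  # ordered base -> loop
    from_loop = stack[::-1]  # closing pair first
    if ed2_offset_from_loop < 1 or len(from_loop) < ed2_offset_from_loop + spacing + 1:
        raise SitesUnassignableError(
            f"stack of {len(from_loop)} pairs too short for ED2 offset "
            f"{ed2_offset_from_loop} + spacing {spacing}"
        )
    ed2 = from_loop[ed2_offset_from_loop - 1]
    # Walk base-ward from ED2; each step must advance the 5' strand by
    # exactly one position (3' bulges leave these steps intact).
    idx = ed2_offset_from_loop - 1
    cur = ed2
    for _ in range(spacing + 1):
        idx += 1
        nxt = from_loop[idx]
        if cur[0] - nxt[0] != 1:
            raise SitesUnassignableError(
                f"5'-strand discontinuity between pairs {nxt} and {cur} "
                f"interrupts the {spacing}-bp spacing count"
            )
        cur = nxt
    ed1 = cur
    seq = annotation.sequence
    if seq is None:
        raise ValueError("annotation carries no sequence; cannot report base identities")
    neighbor = from_loop[idx - 1]  # stacked loop-side of ED1 (e.g. U7-A38)
    return SiteAssignment(
        ed1_pair=ed1,
        ed1_bases=(seq.base(ed1[0]), seq.base(ed1[1])),
        ed2_pair=ed2,
        ed2_bases=(seq.base(ed2[0]), seq.base(ed2[1])),
        spacing_bp=spacing,
        ed2_offset_from_loop=ed2_offset_from_loop,
        ed1_neighbor_pair=neighbor,
    )


TIER_PRIMARY = "primary"
TIER_SUPPORT = "support"
TIER_REJECT = "reject"


@dataclass(frozen=True)
class SignalCandidate:
    span: tuple[int, int]
    annotation: StemLoopAnnotation
    sites: SiteAssignment
    rule_flags: dict[str, bool]
    ed1_score: int
    ed2_score: int
    total_score: int
    tier: str


def score_candidate(
    annotation: StemLoopAnnotation,
    sites: SiteAssignment,
    config: Optional[ScanConfig] = None,
) -> SignalCandidate:
    """Evaluate the recognition rules and assign a tier.

    ``primary`` requires every rule flag (>=6 bp helices flanking the
    internal segment, 3'-strand bulges present, correct spacing) plus
    acceptable pairs at both ED sites.  ``support`` keeps the ED-site
    requirements but relaxes the helix/bulge geometry tied to docking of
    the ExoHD-XAD module, mirroring low-affinity support elements that
    engage ED1 and ED2 only.
    """
    cfg = config or ScanConfig()
    flags = {
        "lower_helix_ge6": len(annotation.lower_helix) >= cfg.min_helix_bp,
        "upper_helix_ge6": len(annotation.upper_helix) >= cfg.min_helix_bp,
        "bulge3_present": len(annotation.internal_segment.bulge3) > 0,
        "spacing_ok": sites.spacing_bp == cfg.spacing,
    }
    ed1 = score_ed_pair(*sites.ed1_bases, ED1, cfg.weights)
    ed2 = score_ed_pair(*sites.ed2_bases, ED2, cfg.weights)
    total = ed1 + ed2 + cfg.geometry_bonus * sum(flags.values())
    # The ED2 site is strictly U-A in every solved signal, so the ED
    # rule demands the top-ranked pair there; ED1 is the variable site
    # (frequently U-A, C-U tolerated) and accepts any positive score.
    ed_ok = ed1 > 0 and ed2 == cfg.weights[("U", "A")]
    if ed_ok and all(flags.values()):
        tier = TIER_PRIMARY
    elif ed_ok and flags["spacing_ok"]:
        tier = TIER_SUPPORT
    else:
        tier = TIER_REJECT
    return SignalCandidate(
        span=annotation.span,
        annotation=annotation,
        sites=sites,
        rule_flags=flags,
        ed1_score=ed1,
        ed2_score=ed2,
        total_score=total,
        tier=tier,
    )


@dataclass(frozen=True)
class TranscriptVerdict:
    candidates: tuple[SignalCandidate, ...]
    coincidence: bool
    best_pair: Optional[tuple[int, int]]


def _best_assignment(
    annotation: StemLoopAnnotation, cfg: ScanConfig
) -> Optional[SignalCandidate]:
    """Best-scoring ED-site placement over the configured offset window.

    Ties break toward the offset closest to the default, then the
    smaller offset.
    """
    best: Optional[SignalCandidate] = None
    best_key = None
    d = cfg.ed2_offset_from_loop
    for offset in range(max(1, d - cfg.offset_window), d + cfg.offset_window + 1):
        try:
            sites = assign_ed_sites(annotation, offset, cfg.spacing)
        except SitesUnassignableError:
            continue
        cand = score_candidate(annotation, sites, cfg)
        key = (-cand.total_score, abs(offset - d), offset)
        if best_key is None or key < best_key:
            best, best_key = cand, key
    return best


def scan_transcript(
    sequence: RnaSequence,
    pair_table: PairTable,
    config: Optional[ScanConfig] = None,
) -> TranscriptVerdict:
    """Enumerate hairpins, score each, and compute the coincidence verdict.

    Coincidence is true when the transcript carries at least one primary
    signal plus at least one additional primary-or-support element —
    the condition for occupying both RNA-binding pockets of the dimer.
    """
    if pair_table.n != len(sequence):
        raise ValueError("pair table does not cover the sequence")
    cfg = config or ScanConfig()
    candidates: list[SignalCandidate] = []
    for span in hairpin_spans(pair_table):
        try:
            ann = annotate_stemloop(pair_table, span, sequence=sequence)
        except NotSimpleStemLoopError:
            continue
        cand = _best_assignment(ann, cfg)
        if cand is not None:
            candidates.append(cand)
    ranked = sorted(
        range(len(candidates)),
        key=lambda k: (-candidates[k].total_score, candidates[k].span),
    )
    primaries = [k for k in ranked if candidates[k].tier == TIER_PRIMARY]
    eligible = [k for k in ranked if candidates[k].tier in (TIER_PRIMARY, TIER_SUPPORT)]
    coincidence = len(candidates) >= 2 and bool(primaries) and len(eligible) >= 2
    best_pair = None
    if coincidence:
        first = primaries[0]
        second = next(k for k in eligible if k != first)
        best_pair = (first, second)
    return TranscriptVerdict(
        candidates=tuple(candidates), coincidence=coincidence, best_pair=best_pair
    )


def verdict_to_records(transcript_id: str, verdict: TranscriptVerdict) -> list[dict]:
    """Flatten a verdict into TSV-ready records."""
    rows = []
    for c in verdict.candidates:
        rows.append(
            {
                "transcript": transcript_id,
                "span_start": c.span[0],
                "span_end": c.span[1],
                "tier": c.tier,
                "ed1_pair": f"{c.sites.ed1_bases[0]}{c.sites.ed1_pair[0]}-"
                f"{c.sites.ed1_bases[1]}{c.sites.ed1_pair[1]}",
                "ed2_pair": f"{c.sites.ed2_bases[0]}{c.sites.ed2_pair[0]}-"
                f"{c.sites.ed2_bases[1]}{c.sites.ed2_pair[1]}",
                "spacing": c.sites.spacing_bp,
                "ed2_offset": c.sites.ed2_offset_from_loop,
                "ed1_score": c.ed1_score,
                "ed2_score": c.ed2_score,
                "total_score": c.total_score,
            }
        )
    return rows
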