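"""Base-pair tables, stem-loop architecture and bulge-deletion constructs.

A hairpin localization signal is decomposed into a lower helix, an
internal segment (a short helix plus strand-specific bulges), an upper
helix and a terminal loop.  Helices are maximal runs of consecutively
stacked pairs — both strands advancing by exactly one per step — and
noncanonical pairs count as stack members, since in empirical structures
bulge/loop nucleotides are frequently integrated into the duplex through
stacking and noncanonical pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import RnaSequence

CANONICAL = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")})

_OPEN = {"(": ")", "[": "]", "{": "}"}
_CLOSE = {v: k for k, v in _OPEN.items()}

MIN_LOOP = 3  # minimum unpaired nucleotides enclosed by any pair


class NotSimpleStemLoopError(ValueError):
    """Raised when a span contains branching (more than one terminal loop)."""


@dataclass(frozen=True)
class PairTable:
    """The base-pairing state of a sequence of length ``n``.

    ``pairs`` holds (i, j) with i < j, 1-based; ``noncanonical`` flags the
    subset that is neither Watson-Crick nor G-U wobble.
    """

    n: int
    pairs: tuple[tuple[int, int], ...]
    noncanonical: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.n):
                raise ValueError(f"pair ({i},{j}) outside 1..{self.n} or unordered")
            if j - i < MIN_LOOP + 1:
                raise ValueError(f"pair ({i},{j}) closes a loop shorter than {MIN_LOOP}")
            if i in seen or j in seen:
                raise ValueError(f"position in pair ({i},{j}) is paired twice")
            seen.update((i, j))
        object.__setattr__(self, "pairs", tuple(sorted(self.pairs)))
        unknown = set(self.noncanonical) - set(self.pairs)
        if unknown:
            raise ValueError(f"noncanonical flags for absent pairs: {sorted(unknown)}")

    def partner(self, i: int) -> Optional[int]:
        for a, b in self.pairs:
            if a == i:
                return b
            if b == i:
                return a
        return None

    def partner_map(self) -> dict[int, int]:
        m: dict[int, int] = {}
        for i, j in self.pairs:
            m[i] = j
            m[j] = i
        return m

    def is_canonical(self, pair: tuple[int, int]) -> bool:
        return pair not in self.noncanonical

    def to_dotbracket(self) -> str:
        """Render as dot-bracket; crossing pairs get a second bracket layer."""
        chars = ["."] * self.n
        layers: list[list[tuple[int, int]]] = [[], []]
        for p in self.pairs:
            placed = False
            for layer in layers:
                if not any(a < p[0] < b < p[1] or p[0] < a < p[1] < b for a, b in layer):
                    layer.append(p)
                    placed = True
                    break
            if not placed:
                raise ValueError("structure needs more than two crossing layers")
        for brackets, layer in zip("([", layers):
            for i, j in layer:
                chars[i - 1] = brackets
                chars[j - 1] = _OPEN[brackets]
        return "".join(chars)


def _classify_pairs(seq: RnaSequence, pairs: list[tuple[int, int]]) -> frozenset:
    return frozenset(
        (i, j) for i, j in pairs if (seq.base(i), seq.base(j)) not in CANONICAL
    )


def build_pair_table(sequence: RnaSequence, dotbracket: str) -> PairTable:
    """Parse dot-bracket into a pair table.

    Supports ``()``, ``[]`` and ``{}`` (pseudoknot-free plus one crossing
    layer).  Pairs are classified canonical (Watson-Crick or G-U) or
    noncanonical (e.g. the C-U pair seen at some ED1 sites) from base
    identities.
    """
    if len(dotbracket) != len(sequence):
        raise ValueError(
            f"sequence length {len(sequence)} != structure length {len(dotbracket)}"
        )
    stacks: dict[str, list[int]] = {b: [] for b in _OPEN}
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(dotbracket, start=1):
        if ch in _OPEN:
            stacks[ch].append(pos)
        elif ch in _CLOSE:
            stack = stacks[_CLOSE[ch]]
            if not stack:
                raise ValueError(f"unmatched closing bracket {ch!r} at position {pos}")
            pairs.append((stack.pop(), pos))
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r} at position {pos}")
    for opener, stack in stacks.items():
        if stack:
            raise ValueError(f"unmatched open bracket {opener!r} at position {stack[0]}")
    return PairTable(
        n=len(sequence), pairs=tuple(pairs), noncanonical=_classify_pairs(sequence, pairs)
    )


_FOLD_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")})


def fold_fallback(sequence: RnaSequence, min_loop: int = MIN_LOOP) -> PairTable:
    """Base-pair maximization (Nussinov dynamic program) over WC + G-U.

    A stand-in for thermodynamic prediction so that the scanner can run
    without an external folder.  The traceback is deterministic: the
    5'-most position is paired whenever pairing is optimal, and among
    optimal partners those that allow the helix to keep stacking are
    preferred, then the 5'-most partner.
    """
    s = sequence.residues
    n = len(s)
    if n < min_loop + 2:
        return PairTable(n=n, pairs=())
    can = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            can[i, j] = (s[i], s[j]) in _FOLD_PAIRS
    dp = np.zeros((n + 1, n + 1), dtype=np.int32)  # dp[i,j] over s[i..j], 0-based incl.
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j]
            ks = np.nonzero(can[i, i : j + 1])[0] + i
            if ks.size:
                cand = 1 + dp[i + 1, ks - 1] + dp[ks + 1, j]
                best = max(best, int(cand.max()))
            dp[i, j] = best
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        target = dp[i, j]
        if target == 0:
            continue
        ks = np.nonzero(can[i, i : j + 1])[0] + i
        best_k = -1
        best_key = None
        for k in ks:
            if 1 + dp[i + 1, k - 1] + dp[k + 1, j] == target:
                stackable = (
                    k - 1 > i + 1 + MIN_LOOP and can[i + 1, k - 1]
                    and 1 + dp[i + 2, k - 2] + 0 <= dp[i + 1, k - 1]
                )
                key = (0 if stackable else 1, k)
                if best_key is None or key < best_key:
                    best_key, best_k = key, int(k)
        if best_k >= 0:
            pairs.append((i + 1, best_k + 1))  # to 1-based
            stack.append((i + 1, best_k - 1))
            stack.append((best_k + 1, j))
        else:
            stack.append((i + 1, j))
    return PairTable(
        n=n, pairs=tuple(pairs), noncanonical=_classify_pairs(sequence, pairs)
    )


@dataclass
class InternalSegment:
    helix_pairs: tuple[tuple[int, int], ...] = ()
    bulge5: tuple[int, ...] = ()  # unpaired 5'-strand positions
    bulge3: tuple[int, ...] = ()  # unpaired 3'-strand positions


@dataclass
class StemLoopAnnotation:
    """Partition of a hairpin span into architectural components.

    ``lower_helix`` and ``upper_helix`` are ordered base -> loop; the
    internal segment holds any short intervening helix plus unpaired
    bulges labelled by strand.  Every position of the span belongs to
    exactly one component.
    """

    span: tuple[int, int]
    lower_helix: tuple[tuple[int, int], ...]
    internal_segment: InternalSegment
    upper_helix: tuple[tuple[int, int], ...]
    terminal_loop: tuple[int, ...]
    closing_pair: tuple[int, int]
    sequence: Optional[RnaSequence] = None
    noncanonical: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    @property
    def stack(self) -> tuple[tuple[int, int], ...]:
        """All stacked pairs ordered base -> loop."""
        return self.lower_helix + self.internal_segment.helix_pairs + self.upper_helix

    def to_dict(self) -> dict:
        return {
            "span": list(self.span),
            "lower_helix": [list(p) for p in self.lower_helix],
            "internal_helix": [list(p) for p in self.internal_segment.helix_pairs],
            "bulge5": list(self.internal_segment.bulge5),
            "bulge3": list(self.internal_segment.bulge3),
            "upper_helix": [list(p) for p in self.upper_helix],
            "terminal_loop": list(self.terminal_loop),
            "closing_pair": list(self.closing_pair),
            "noncanonical": [list(p) for p in sorted(self.noncanonical)],
        }


def annotate_stemloop(
    pair_table: PairTable,
    hairpin_span: Optional[tuple[int, int]] = None,
    sequence: Optional[RnaSequence] = None,
) -> StemLoopAnnotation:
    """Partition a single-hairpin span into helices, bulges and loop.

    The span must enclose exactly one terminal loop; branching raises
    :class:`NotSimpleStemLoopError`.  A bulge-free hairpin is returned
    with the full stack in ``lower_helix`` and an empty upper helix:
    upper/lower is only meaningful relative to an internal segment.
    """
    if hairpin_span is None:
        hairpin_span = (1, pair_table.n)
    lo, hi = hairpin_span
    inside = sorted(p for p in pair_table.pairs if lo <= p[0] and p[1] <= hi)
    if not inside:
        raise NotSimpleStemLoopError(f"span {hairpin_span} contains no pairs")
    # Simple stem: pairs sorted by i must be strictly nested in sequence.
    for (i1, j1), (i2, j2) in zip(inside, inside[1:]):
        if not (i1 < i2 < j2 < j1):
            raise NotSimpleStemLoopError(
                f"span {hairpin_span} is not a simple stem loop: "
                f"pairs ({i1},{j1}) and ({i2},{j2}) are not nested"
            )
    outer_i, outer_j = inside[0]
    closing = inside[-1]
    loop = tuple(range(closing[0] + 1, closing[1]))
    # Maximal stacked runs: both strands advance by exactly one per step.
    runs: list[list[tuple[int, int]]] = [[inside[0]]]
    for prev, cur in zip(inside, inside[1:]):
        if cur[0] == prev[0] + 1 and cur[1] == prev[1] - 1:
            runs[-1].append(cur)
        else:
            runs.append([cur])
    if len(runs) == 1:
        lower, internal_runs, upper = runs[0], [], []
    else:
        lower, internal_runs, upper = runs[0], runs[1:-1], runs[-1]
    paired_pos = {p for pr in inside for p in pr}
    # Unpaired positions between the lower and upper helices, by strand.
    top_of_lower = lower[-1]
    base_of_upper = upper[0] if upper else closing
    bulge5 = tuple(
        p for p in range(top_of_lower[0] + 1, base_of_upper[0]) if p not in paired_pos
    )
    bulge3 = tuple(
        p for p in range(base_of_upper[1] + 1, top_of_lower[1]) if p not in paired_pos
    )
    ann = StemLoopAnnotation(
        span=(outer_i, outer_j),
        lower_helix=tuple(lower),
        internal_segment=InternalSegment(
            helix_pairs=tuple(p for run in internal_runs for p in run),
            bulge5=bulge5,
            bulge3=bulge3,
        ),
        upper_helix=tuple(upper),
        terminal_loop=loop,
        closing_pair=closing,
        sequence=sequence,
        noncanonical=frozenset(p for p in pair_table.noncanonical if p in set(inside)),
    )
    return ann


def hairpin_spans(pair_table: PairTable) -> list[tuple[int, int]]:
    """Maximal simple-stem spans, one per terminal loop.

    Each span extends from a terminal (innermost) pair outward through
    enclosing pairs as long as each encloses only that one hairpin,
    stopping at multiloop branch points.
    """
    pairs = sorted(pair_table.pairs)
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pairs}
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    stack: list[tuple[int, int]] = []
    for p in pairs:
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        if stack:
            parent[p] = stack[-1]
            children[stack[-1]].append(p)
        stack.append(p)
    spans = []
    for p in pairs:
        if children[p]:
            continue  # not a terminal pair
        cur = p
        while cur in parent and len(children[parent[cur]]) == 1:
            cur = parent[cur]
        spans.append((cur[0], cur[1]))
    return sorted(spans)


def delete_bulges(
    sequence: RnaSequence, annotation: StemLoopAnnotation
) -> tuple[RnaSequence, PairTable]:
    """Remove bulged nucleotides and renumber, fusing the helices.

    Mirrors the construction of bulge-deletion (Δb) variants, where the
    nucleotides to remove are chosen from the experimentally annotated
    architecture rather than from a secondary-structure prediction.
    Idempotent: a bulge-free annotation maps to itself.
    """
    drop = set(annotation.internal_segment.bulge5) | set(annotation.internal_segment.bulge3)
    keep = [p for p in range(1, len(sequence) + 1) if p not in drop]
    new_index = {old: new for new, old in enumerate(keep, start=1)}
    new_seq = RnaSequence(
        id=sequence.id + ("_db" if drop else ""),
        residues="".join(sequence.base(p) for p in keep),
    )
    old_pairs = annotation.stack
    new_pairs = tuple((new_index[i], new_index[j]) for i, j in old_pairs)
    noncanonical = frozenset(
        (new_index[i], new_index[j]) for i, j in annotation.noncanonical
    )
    return new_seq, PairTable(n=len(new_seq), pairs=new_pairs, noncanonical=noncanonical)
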