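"""Anchor-gene alignment, homogeneity grouping and degenerate primer design.

The design chain: align the anchor tRNA sequences harvested by the survey
(center-star multiple alignment), split them into groups with high internal
homogeneity over a central window (complete-linkage clustering on pairwise
identity), collapse each group into an IUPAC degenerate consensus, and turn
a consensus into a PCR primer — optionally resolving residual degenerate
positions to single bases, appending a 5' sequencing tail (e.g. M13) and
preferring a G/C 3' terminus, which improves priming efficiency.

Center-star alignment is used instead of a progressive aligner: anchor
tRNAs are short (20-100 nt) and near-equal length, a regime where the
center-star heuristic is accurate and keeps the package self-contained.
Externally aligned FASTA can be supplied instead (any equal-length rows
form a valid :class:`AlignedBlock`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from . import iupac
from .iupac import IUPACError, bases, code_for, degeneracy, validate

GAP = "-"


@dataclass
class AlignedBlock:
    """Equal-length gapped rows over {A,C,G,T,N,-}."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"rows have unequal widths: {sorted(widths)}")
        self.rows = [validate(r, allow_gap=True) for r in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def central_window(self, width: int) -> tuple[int, int]:
        """The centered column window of the given width (clipped)."""
        width = min(width, self.n_columns)
        start = (self.n_columns - width) // 2
        return (start, start + width)


@dataclass
class DegenerateConsensus:
    """IUPAC consensus with the per-position base-frequency table behind it."""

    iupac: str
    freq: list[dict[str, float]]

    def __len__(self) -> int:
        return len(self.iupac)


@dataclass
class HomogeneityGroup:
    member_ids: list[str]
    central_window: tuple[int, int]
    consensus: DegenerateConsensus


@dataclass
class PrimerSpec:
    """A (possibly degenerate) PCR primer: core + optional 5' tail.

    Only the core participates in template matching; the tail (a sequencing
    adapter such as M13) rides along 5' of it.
    """

    name: str
    core: str
    tail: str | None = None
    direction: str = "forward"
    degeneracy: int = field(init=False)

    def __post_init__(self):
        self.core = validate(self.core)
        if self.tail is not None:
            self.tail = validate(self.tail)
        if self.direction not in ("forward", "reverse"):
            raise ValueError("direction must be 'forward' or 'reverse'")
        self.degeneracy = degeneracy(self.core)

    @property
    def three_prime_base(self) -> str:
        return self.core[-1]

    @property
    def full_oligo(self) -> str:
        return (self.tail or "") + self.core


# ---------------------------------------------------------------------------
# center-star multiple alignment


def _nw_pair(a: str, b: str) -> tuple[str, str]:
    """Global pairwise alignment minimizing edit distance.

    Traceback prefers substitution over indels, so equal-length inputs align
    gap-free; among indels, gaps in ``b`` are taken before gaps in ``a``.
    """
    n, m = len(a), len(b)
    D = np.zeros((n + 1, m + 1), dtype=np.int32)
    D[:, 0] = np.arange(n + 1)
    D[0, :] = np.arange(m + 1)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        sub = D[i - 1, :-1] + (bv != ord(a[i - 1]))
        row = D[i]
        row[0] = i
        prev = D[i - 1]
        for j in range(1, m + 1):  # indel recurrence is sequential
            row[j] = min(sub[j - 1], prev[j] + 1, row[j - 1] + 1)
    ga, gb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + (a[i - 1] != b[j - 1]):
            ga.append(a[i - 1]); gb.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and D[i, j] == D[i - 1, j] + 1:
            ga.append(a[i - 1]); gb.append(GAP); i -= 1
        else:
            ga.append(GAP); gb.append(b[j - 1]); j -= 1
    return "".join(reversed(ga)), "".join(reversed(gb))


def center_star_msa(
    sequences: list[str], ids: list[str] | None = None
) -> AlignedBlock:
    """Center-star multiple alignment of short sequences.

    The center is the sequence minimizing its summed pairwise edit distance
    to all others (ties by input order); every other sequence is aligned to
    it pairwise and the alignments are merged under "once a gap, always a
    gap". Row order follows input order.
    """
    if len(sequences) < 2:
        raise ValueError("center-star alignment needs at least 2 sequences")
    sequences = [validate(s) for s in sequences]
    if ids is None:
        ids = [f"seq{i}" for i in range(len(sequences))]
    n = len(sequences)
    totals = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(sequences[i], sequences[j])["editDistance"]
            totals[i] += d
            totals[j] += d
    center_idx = int(np.argmin(totals))
    center = sequences[center_idx]

    master = list(center)  # gapped center
    aligned: list[list[str]] = []  # rows for non-center seqs, in master coords
    order: list[int] = []
    for idx, seq in enumerate(sequences):
        if idx == center_idx:
            continue
        cg, sg = _nw_pair(center, seq)
        # merge cg (gapped center) into master, padding rows already placed
        new_master: list[str] = []
        new_row: list[str] = []
        merged_rows: list[list[str]] = [[] for _ in aligned]
        i = j = 0
        while i < len(master) or j < len(cg):
            mi = master[i] if i < len(master) else None
            cj = cg[j] if j < len(cg) else None
            if mi == GAP and cj != GAP:
                new_master.append(GAP)
                new_row.append(GAP)
                for r, mr in zip(aligned, merged_rows):
                    mr.append(r[i])
                i += 1
            elif cj == GAP and mi != GAP:
                new_master.append(GAP)
                new_row.append(sg[j])
                for mr in merged_rows:
                    mr.append(GAP)
                j += 1
            else:  # both gaps or both the same center base
                new_master.append(mi)
                new_row.append(sg[j])
                for r, mr in zip(aligned, merged_rows):
                    mr.append(r[i])
                i += 1
                j += 1
        master = new_master
        aligned = merged_rows
        aligned.append(new_row)
        order.append(idx)

    rows_by_idx = {center_idx: "".join(master)}
    for idx, row in zip(order, aligned):
        rows_by_idx[idx] = "".join(row)
    return AlignedBlock(ids=list(ids), rows=[rows_by_idx[i] for i in range(n)])


# ---------------------------------------------------------------------------
# homogeneity grouping


def _pair_identity(a: str, b: str, window: tuple[int, int]) -> float:
    """Identity of two gapped rows over a column window.

    Computed on the rows' ungapped subsequences within the window as
    1 - d/l (d = edit distance, l = longer subsequence), which makes the
    measure insensitive to where the aligner happened to place gaps.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty column window")
    wa = a[lo:hi].replace(GAP, "")
    wb = b[lo:hi].replace(GAP, "")
    longer = max(len(wa), len(wb))
    if longer == 0:
        return 1.0
    d = edlib.align(wa, wb)["editDistance"]
    return 1.0 - d / longer


def partition_groups(
    block: AlignedBlock,
    window: tuple[int, int] | None = None,
    identity_threshold: float = 0.75,
    min_freq: float = 0.05,
) -> list[HomogeneityGroup]:
    """Split aligned rows into internal-homogeneity groups.

    Complete-linkage agglomerative clustering on pairwise identity over the
    column window (default: the central 19 columns): repeatedly merge the
    cluster pair whose *minimum* pairwise identity is highest, as long as
    that minimum stays at or above ``identity_threshold``. Ties break on the
    lowest member index, making the partition independent of input order.
    Each group carries the degenerate consensus of its window.
    """
    if window is None:
        window = block.central_window(19)
    lo, hi = window
    if not (0 <= lo < hi <= block.n_columns):
        raise ValueError(f"window {window} empty or outside block columns")
    n = len(block.rows)
    ident = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = _pair_identity(
                block.rows[i], block.rows[j], window
            )
    clusters: list[list[int]] = [[i] for i in range(n)]
    while True:
        best = None  # (similarity, min_id_a, min_id_b, ia, ib)
        for ia in range(len(clusters)):
            for ib in range(ia + 1, len(clusters)):
                sim = min(
                    ident[x, y] for x in clusters[ia] for y in clusters[ib]
                )
                a0, b0 = clusters[ia][0], clusters[ib][0]
                key = (-sim, min(a0, b0), max(a0, b0))
                if sim >= identity_threshold and (best is None or key < best[0]):
                    best = (key, ia, ib)
        if best is None:
            break
        _, ia, ib = best
        merged = sorted(clusters[ia] + clusters[ib])
        clusters = [c for k, c in enumerate(clusters) if k not in (ia, ib)]
        clusters.append(merged)
    clusters.sort(key=lambda c: (-len(c), c[0]))
    groups = []
    for members in clusters:
        cons = degenerate_consensus(
            [block.rows[i] for i in members],
            window=window,
            min_freq=min_freq,
            skip_all_gap_columns=True,
        )
        groups.append(
            HomogeneityGroup(
                member_ids=[block.ids[i] for i in members],
                central_window=window,
                consensus=cons,
            )
        )
    return groups


# ---------------------------------------------------------------------------
# degenerate consensus


def degenerate_consensus(
    rows: list[str],
    window: tuple[int, int] | None = None,
    min_freq: float = 0.05,
    skip_all_gap_columns: bool = False,
) -> DegenerateConsensus:
    """Collapse aligned rows into an IUPAC degenerate consensus.

    Per column, gaps are excluded and each symbol contributes weight
    ``1/|base set|`` to every base it can stand for (so N counts 1/4 toward
    each base). Bases with relative frequency >= ``min_freq`` (and > 0) enter
    the code set; if the cutoff would empty the set, the maximal-frequency
    bases are kept so a code always exists.
    """
    if not rows:
        raise ValueError("need at least one row")
    if not (0 <= min_freq < 1):
        raise ValueError("min_freq must be in [0, 1)")
    rows = [validate(r, allow_gap=True) for r in rows]
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("rows have unequal widths")
    lo, hi = window if window is not None else (0, width)
    out = []
    freqs: list[dict[str, float]] = []
    for col in range(lo, hi):
        weights = {"A": 0.0, "C": 0.0, "G": 0.0, "T": 0.0}
        n_nongap = 0
        for r in rows:
            c = r[col]
            if c == GAP:
                continue
            n_nongap += 1
            bs = bases(c)
            w = 1.0 / len(bs)
            for b in bs:
                weights[b] += w
        if n_nongap == 0:
            if skip_all_gap_columns:
                continue
            raise ValueError(f"column {col} is all gaps")
        freq = {b: w / n_nongap for b, w in weights.items()}
        chosen = {b for b, f in freq.items() if f > 0 and f >= min_freq}
        if not chosen:
            top = max(freq.values())
            chosen = {b for b, f in freq.items() if f == top}
        out.append(code_for(chosen))
        freqs.append(freq)
    return DegenerateConsensus("".join(out), freqs)


# ---------------------------------------------------------------------------
# primer construction


def design_primer(
    consensus: DegenerateConsensus | str,
    core_length: int | None = None,
    resolution_map: dict[int, str] | None = None,
    tail: str | None = None,
    prefer_3prime_GC: bool = True,
    three_prime_extension: str = "",
    name: str = "primer",
    direction: str = "forward",
) -> PrimerSpec:
    """Turn a degenerate consensus into a primer.

    ``resolution_map`` maps 1-based consensus positions to a single base
    replacing the degenerate code there (the base must belong to the code's
    set) — this captures deliberate, non-algorithmic resolutions made when a
    mixed base would cost too much degeneracy. When ``prefer_3prime_GC`` is
    set and the consensus contains a G/C/S position, the core is placed so
    it ends on the rightmost such position (a G or C 3' terminus primes more
    efficiently); otherwise it ends at the consensus 3' end.
    ``three_prime_extension`` appends extra 3' bases after the core.
    """
    seq = consensus.iupac if isinstance(consensus, DegenerateConsensus) else validate(consensus)
    if core_length is not None and core_length > len(seq):
        raise ValueError("core_length exceeds consensus length")
    if resolution_map:
        chars = list(seq)
        for pos, base in resolution_map.items():
            if not (1 <= pos <= len(seq)):
                raise ValueError(f"resolution position {pos} outside consensus")
            base = base.upper()
            if base not in bases(seq[pos - 1]):
                raise ValueError(
                    f"resolution base {base} not in code {seq[pos - 1]} "
                    f"at position {pos}"
                )
            chars[pos - 1] = base
        seq = "".join(chars)
    end = len(seq)
    if prefer_3prime_GC:
        gc_positions = [i for i, c in enumerate(seq) if c in "GCS"]
        if gc_positions:
            end = gc_positions[-1] + 1
    # default: the longest core that fits before the chosen 3' end
    start = 0 if core_length is None else end - core_length
    if start < 0:
        raise ValueError(
            f"core_length {core_length} does not fit before position {end}"
        )
    core = seq[start:end] + validate(three_prime_extension)
    return PrimerSpec(name=name, core=core, tail=tail, direction=direction)


def derive_rescue_primer(
    failing_templates: list[str],
    binding_window: tuple[int, int],
    min_freq: float = 0.0,
    name: str = "rescue",
    ids: list[str] | None = None,
) -> PrimerSpec:
    """Design a group-specific forward primer from failing templates.

    Windows the given 5' sequences on the standard primer's binding interval
    (template coordinates, gap-free by construction) and collapses them into
    a degenerate consensus, returned as a forward primer. This is how a
    rescue primer for a taxon that resists the universal primers is built
    once the anchor cocktail has exposed its true binding-site sequence.
    """
    if len(failing_templates) < 2:
        raise ValueError("need at least 2 templates")
    lo, hi = binding_window
    if ids is None:
        ids = [f"t{i}" for i in range(len(failing_templates))]
    short = [i for t, i in zip(failing_templates, ids) if len(t) < hi]
    if short:
        raise ValueError(
            f"templates not covering window [{lo}, {hi}): {', '.join(short)}"
        )
    rows = [validate(t)[lo:hi] for t in failing_templates]
    cons = degenerate_consensus(rows, min_freq=min_freq)
    return PrimerSpec(name=name, core=cons.iupac, direction="forward")


def primer_tm(primer: PrimerSpec) -> tuple[float, float]:
    """Wallace-rule melting-temperature range, 2(A+T) + 4(G+C), in Celsius.

    Evaluated over the minimum-GC and maximum-GC concrete expansions of the
    degenerate core; the tail is excluded.
    """
    if len(primer.core) < 10:
        raise ValueError("Tm rule needs a core of at least 10 nt")
    tmin = tmax = 0
    for c in primer.core:
        bs = bases(c)
        has_at = bool(bs & {"A", "T"})
        has_gc = bool(bs & {"G", "C"})
        tmin += 2 if has_at else 4
        tmax += 4 if has_gc else 2
    return (float(tmin), float(tmax))


# ---------------------------------------------------------------------------
# printed sequences of the study (inputs for reproduction, not ground truth
# for any algorithm): the two anchor-group consensi, the M13 sequencing
# tail, the deliberate degeneracy resolutions behind the two anchor primers,
# and the scale-insect rescue primer.

GROUP1_CONSENSUS = "AAACTAWNARCCTTCAAAG"
GROUP2_CONSENSUS = "AAACTANWRATYTTCAAAATY"
M13_TAIL = "TGTAAAACGACGGCCAGT"
TRWF1_RESOLUTION = {7: "A", 8: "T"}
TRWF2_RESOLUTION = {7: "A", 8: "T", 9: "A", 21: "T"}
PCOF1_CORE = "CCTTCAACTAATCATAAAAATATYAG"


def trwf1(tail: str | None = M13_TAIL) -> PrimerSpec:
    """The group-1 anchor primer, rebuilt from consensus + resolutions."""
    return design_primer(
        GROUP1_CONSENSUS,
        core_length=19,
        resolution_map=TRWF1_RESOLUTION,
        tail=tail,
        prefer_3prime_GC=True,
        name="tRWF1",
    )


def trwf2(tail: str | None = M13_TAIL) -> PrimerSpec:
    """The group-2 anchor primer: resolutions plus a 1-nt 3' extension."""
    return design_primer(
        GROUP2_CONSENSUS,
        core_length=21,
        resolution_map=TRWF2_RESOLUTION,
        tail=tail,
        prefer_3prime_GC=False,
        three_prime_extension="A",
        name="tRWF2",
    )


def pcof1() -> PrimerSpec:
    return PrimerSpec(name="PcoF1", core=PCOF1_CORE, direction="forward")
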