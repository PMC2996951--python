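"""Gene-arrangement survey upstream of a target gene.

Mitochondrial gene order varies across arthropods, but a short run of tRNA
genes (typically trnW, often followed by reverse-oriented trnC and trnY)
sits directly upstream of COI in most lineages. This module extracts that
local arrangement as a signed token string (e.g. ``W,-C,-Y``; the minus sign
marks reverse orientation relative to the target), tabulates arrangement
frequencies over a set of genomes, and ranks candidate anchor genes by
positional stability — the analysis that motivates siting a universal
forward primer inside trnW.

Orientation is always expressed relative to the target gene's strand:
records whose target lies on the reverse strand are reverse-complemented
first, so a single forward-strand code path serves both cases.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .records import GeneFeature, MitoGenome, Thresholds

NO_TARGET = "<no target>"

# Table-notation token: drop a leading "trn" prefix so trnW renders as W.
def _render_token(name: str) -> str:
    return name[3:] if name.startswith("trn") and len(name) > 3 else name


def _unrender_token(tok: str) -> str:
    return f"trn{tok}" if len(tok) == 1 else tok


@dataclass(frozen=True)
class ArrangementString:
    """Signed gene order 5'->3' toward the target (most distal first)."""

    tokens: tuple[tuple[str, int], ...]  # (gene token, +1/-1)

    def render(self) -> str:
        return ",".join(
            ("-" if sign == -1 else "") + _render_token(name)
            for name, sign in self.tokens
        )

    @classmethod
    def parse(cls, text: str) -> "ArrangementString":
        text = text.strip()
        if not text:
            return cls(())
        toks = []
        for piece in text.split(","):
            piece = piece.strip()
            sign = -1 if piece.startswith("-") else 1
            toks.append((_unrender_token(piece.lstrip("-")), sign))
        return cls(tuple(toks))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass(frozen=True)
class AnchorCandidate:
    """One gene's summary as a potential primer anchor."""

    gene: str
    distance_bp: int
    orientation: int
    eligible: bool
    presence_fraction: float = 0.0
    forward_fraction: float = 0.0


@dataclass
class ArrangementTabulation:
    """Frequency table of arrangements plus per-gene anchor statistics."""

    arrangements: pd.DataFrame  # columns: arrangement, count, fraction
    gene_summary: pd.DataFrame  # columns: gene, n_present, n_forward, median_distance
    n_genomes: int
    distances: dict[str, list[int]] = field(default_factory=dict)


def extract_upstream_arrangement(
    genome: MitoGenome, target: str, window_bp: int = 200
) -> ArrangementString:
    """Signed arrangement of genes inside ``window_bp`` upstream of ``target``.

    A feature is included when its strand-aware 3' end falls inside the
    window; partially overlapping features whose 3' end lies outside are
    dropped. Tokens run from most distal to most proximal.
    """
    hits = genome.features_named(target)
    if not hits:
        raise ValueError(f"genome {genome.id}: target {target!r} not found")
    if len(hits) > 1:
        spans = ", ".join(f"[{f.start}, {f.end})" for f in hits)
        raise ValueError(
            f"genome {genome.id}: target {target!r} present in two or more "
            f"copies: {spans}"
        )
    tgt = hits[0]
    if tgt.strand == -1:
        return extract_upstream_arrangement(
            genome.reverse_complemented(), target, window_bp
        )
    lo = tgt.start - window_bp
    toks = []
    for f in genome.features:
        if f is tgt or f.name == target:
            continue
        if f.end > tgt.start:  # not upstream
            continue
        tp = f.three_prime()
        if lo <= tp <= tgt.start:
            toks.append((f.name, f.strand))
    return ArrangementString(tuple(toks))


def anchor_distance(genome: MitoGenome, anchor: GeneFeature, target: GeneFeature) -> int:
    """Gap between the anchor's strand-aware 3' end and the target start."""
    return target.start - anchor.three_prime()


def tabulate_arrangements(
    genomes: list[MitoGenome], target: str, window_bp: int = 200
) -> ArrangementTabulation:
    """Tabulate distinct upstream arrangements and per-gene anchor stats.

    Genomes lacking the target are counted under a ``<no target>`` row. The
    gene summary records, for each gene seen upstream of the target, in how
    many genomes it appears, in how many it is forward-oriented, and its
    median 3'-end-to-target distance.
    """
    if not genomes:
        raise ValueError("need at least one genome")
    counts: dict[str, int] = {}
    present: dict[str, int] = {}
    forward: dict[str, int] = {}
    distances: dict[str, list[int]] = {}
    for g in genomes:
        try:
            arr = extract_upstream_arrangement(g, target, window_bp)
        except ValueError:
            counts[NO_TARGET] = counts.get(NO_TARGET, 0) + 1
            continue
        key = arr.render()
        counts[key] = counts.get(key, 0) + 1
        gg = g if g.features_named(target)[0].strand == 1 else g.reverse_complemented()
        tgt = gg.features_named(target)[0]
        seen_here = set()
        for name, sign in arr.tokens:
            if name in seen_here:
                continue
            seen_here.add(name)
            present[name] = present.get(name, 0) + 1
            if sign == 1:
                forward[name] = forward.get(name, 0) + 1
            # distance of the proximal-most copy of this gene
            feats = [
                f
                for f in gg.features
                if f.name == name and f.end <= tgt.start
            ]
            if feats:
                distances.setdefault(name, []).append(
                    anchor_distance(gg, feats[-1], tgt)
                )
    n = len(genomes)
    arr_df = (
        pd.DataFrame(
            {"arrangement": list(counts), "count": list(counts.values())}
        )
        .assign(fraction=lambda d: d["count"] / n)
        .sort_values(["count", "arrangement"], ascending=[False, True])
        .reset_index(drop=True)
    )
    genes = sorted(present)
    gene_df = pd.DataFrame(
        {
            "gene": genes,
            "n_present": [present[g] for g in genes],
            "n_forward": [forward.get(g, 0) for g in genes],
            "median_distance": [
                statistics.median(distances[g]) if distances.get(g) else float("nan")
                for g in genes
            ],
        }
    )
    return ArrangementTabulation(arr_df, gene_df, n, distances)


def select_anchor(
    tab: ArrangementTabulation, thresholds: Thresholds = Thresholds()
) -> list[AnchorCandidate]:
    """Rank candidate anchor genes by positional stability.

    Ranking is lexicographic: presence fraction (desc), forward-orientation
    fraction (desc), median distance (asc), gene token (asc). A candidate is
    eligible when its modal orientation is forward and its median distance
    does not exceed ``max_anchor_distance_bp``.
    """
    if tab.gene_summary.empty:
        warnings.warn("no upstream genes observed; empty anchor ranking")
        return []
    out = []
    for _, row in tab.gene_summary.iterrows():
        pres = row["n_present"] / tab.n_genomes
        fwd = row["n_forward"] / row["n_present"] if row["n_present"] else 0.0
        orient = 1 if fwd >= 0.5 else -1
        med = row["median_distance"]
        eligible = (
            orient == 1
            and med == med  # not NaN
            and med <= thresholds.max_anchor_distance_bp
        )
        out.append(
            AnchorCandidate(
                gene=row["gene"],
                distance_bp=int(med) if med == med else -1,
                orientation=orient,
                eligible=eligible,
                presence_fraction=pres,
                forward_fraction=fwd,
            )
        )
    out.sort(key=lambda c: (-c.presence_fraction, -c.forward_fraction, c.distance_bp, c.gene))
    if not any(c.eligible for c in out):
        warnings.warn("no eligible anchor candidate under the given thresholds")
        return []
    return out
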