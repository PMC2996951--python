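"""IUPAC-aware in-silico PCR: site scanning, mismatch profiling, prediction.

Primer/template matching is symmetric set-intersection over IUPAC codes
(template N matches everything). Amplification prediction operationalizes
the empirical failure pattern seen when standard barcode primers meet
divergent binding sites: a primer fails on a template when its 3'-terminal
base mismatches, or when the 3'-weighted mismatch score — total mismatches
plus an extra count for each mismatch within the last ``three_prime_window_nt``
bases — exceeds ``mismatch_fail_count``. Tails never take part in matching,
and amplicon lengths include both primer footprints, matching how sequenced
amplicon lengths are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iupac import CODE_TO_BASES, IUPACError, reverse_complement, validate
from .consensus import PrimerSpec
from .records import Thresholds

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_MASK = {c: sum(_BASE_BIT[b] for b in bs) for c, bs in CODE_TO_BASES.items()}


def iupac_compatible(a: str, b: str) -> bool:
    """True iff two IUPAC codes share at least one concrete base."""
    a, b = a.upper(), b.upper()
    if a not in _CODE_MASK or b not in _CODE_MASK:
        bad = a if a not in _CODE_MASK else b
        raise IUPACError(f"not an IUPAC nucleotide code: {bad!r}")
    return bool(_CODE_MASK[a] & _CODE_MASK[b])


def _mask_array(seq: str) -> np.ndarray:
    return np.array([_CODE_MASK[c] for c in seq], dtype=np.uint8)


@dataclass
class MatchResult:
    """One footprint of a primer core on a template.

    Coordinates are on the forward template strand regardless of which
    strand was scanned; per-position flags are in core coordinates, 5'->3'
    along the primer.
    """

    primer: str
    template_pos: int
    strand: str  # '+' or '-'
    per_pos_mismatch: list[bool]
    mismatch_count: int = field(init=False)
    min_dist_to_3prime: int | None = field(init=False)
    terminal_mismatch: bool = field(init=False)
    core_length: int = field(init=False)

    def __post_init__(self):
        flags = self.per_pos_mismatch
        self.core_length = len(flags)
        self.mismatch_count = sum(flags)
        self.terminal_mismatch = bool(flags[-1]) if flags else False
        mism = [i for i, f in enumerate(flags) if f]
        self.min_dist_to_3prime = (
            self.core_length - 1 - mism[-1] if mism else None
        )

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.template_pos, self.template_pos + self.core_length)

    def weighted_score(self, thresholds: Thresholds = Thresholds()) -> int:
        """Mismatch count with 3'-window mismatches counted double."""
        w = thresholds.three_prime_window_nt
        extra = sum(
            1
            for i, f in enumerate(self.per_pos_mismatch)
            if f and (self.core_length - 1 - i) < w
        )
        return self.mismatch_count + extra

    def fails(self, thresholds: Thresholds = Thresholds()) -> bool:
        return self.terminal_mismatch or (
            self.weighted_score(thresholds) > thresholds.mismatch_fail_count
        )


@dataclass
class AmpliconPrediction:
    success: bool
    reasons: list[str]
    amplicon: tuple[int, int] | None
    length_bp: int | None


def scan_primer(
    primer: PrimerSpec,
    template: str,
    strand: str = "+",
    max_mismatch: int = 3,
) -> list[MatchResult]:
    """All footprints of the primer core with at most ``max_mismatch``
    incompatible positions, sorted by forward-strand position.

    On strand '-', the core is matched against the reverse complement and
    footprints are mapped back to forward coordinates.
    """
    template = validate(template)
    core = primer.core
    L = len(core)
    if len(template) < L:
        raise ValueError("template shorter than primer core")
    scan_seq = template if strand == "+" else reverse_complement(template)
    tmpl = _mask_array(scan_seq)
    pmask = _mask_array(core)
    windows = np.lib.stride_tricks.sliding_window_view(tmpl, L)
    mism = (windows & pmask) == 0  # (n_pos, L) boolean
    counts = mism.sum(axis=1)
    out = []
    for pos in np.nonzero(counts <= max_mismatch)[0]:
        pos = int(pos)
        fwd_pos = pos if strand == "+" else len(template) - pos - L
        out.append(
            MatchResult(
                primer=primer.name,
                template_pos=fwd_pos,
                strand=strand,
                per_pos_mismatch=[bool(x) for x in mism[pos]],
            )
        )
    out.sort(key=lambda m: m.template_pos)
    return out


def predict_amplification(
    fwd_hit: MatchResult | None,
    rev_hit: MatchResult | None,
    thresholds: Thresholds = Thresholds(),
) -> AmpliconPrediction:
    """Combine one forward and one reverse footprint into a success call.

    Either hit may be None (no binding site found), yielding NO_SITE /
    NO_REVERSE_SITE. The amplicon runs from the forward footprint start to
    the reverse footprint end (primer footprints included).
    """
    reasons: list[str] = []
    if fwd_hit is None:
        reasons.append("NO_SITE")
    if rev_hit is None:
        reasons.append("NO_REVERSE_SITE")
    if reasons:
        return AmpliconPrediction(False, reasons, None, None)
    if rev_hit.footprint[0] < fwd_hit.footprint[1]:
        raise ValueError(
            "reverse footprint must lie 3' of the forward footprint"
        )
    for hit in (fwd_hit, rev_hit):
        if hit.terminal_mismatch:
            reasons.append("TERMINAL_3PRIME_MISMATCH")
        if hit.weighted_score(thresholds) > thresholds.mismatch_fail_count:
            reasons.append("TOO_MANY_MISMATCHES")
    reasons = sorted(set(reasons))
    start = fwd_hit.footprint[0]
    end = rev_hit.footprint[1]
    return AmpliconPrediction(
        success=not reasons,
        reasons=reasons,
        amplicon=(start, end),
        length_bp=end - start,
    )


def best_footprint(
    primer: PrimerSpec, template: str, strand: str = "+"
) -> MatchResult:
    """The unique minimum-mismatch footprint; error on a tie."""
    hits = scan_primer(primer, template, strand=strand, max_mismatch=len(primer.core))
    best_count = min(h.mismatch_count for h in hits)
    ties = [h for h in hits if h.mismatch_count == best_count]
    if len(ties) > 1:
        pos = ", ".join(str(h.template_pos) for h in ties)
        raise ValueError(
            f"ambiguous best footprint for {primer.name}: tied positions {pos}"
        )
    return ties[0]


def profile_binding_site(
    primer: PrimerSpec,
    templates: list[tuple[str, str]],
    strand: str = "+",
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Per-template substitution table at the primer's best binding site.

    One row per mismatch: template id, 0-based position in primer
    coordinates, the primer's IUPAC code, the template base there, and
    whether the position falls in the 3' window. Empty table when every
    template matches an expansion of the primer.
    """
    rows = []
    w = thresholds.three_prime_window_nt
    for tid, seq in templates:
        hit = best_footprint(primer, seq, strand=strand)
        scan_seq = seq if strand == "+" else reverse_complement(seq)
        pos0 = (
            hit.template_pos
            if strand == "+"
            else len(seq) - hit.template_pos - hit.core_length
        )
        site = scan_seq[pos0 : pos0 + hit.core_length]
        for i, f in enumerate(hit.per_pos_mismatch):
            if f:
                rows.append(
                    {
                        "template": tid,
                        "position": i,
                        "primer_code": primer.core[i],
                        "template_base": site[i],
                        "in_3prime_window": (hit.core_length - 1 - i) < w,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["template", "position", "primer_code", "template_base", "in_3prime_window"],
    )
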