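"""Post-amplification COI barcode quality control.

Reads produced with a tRNA-anchored forward primer begin with 70-200 bp of
tRNA-derived sequence that must be excised before the COI open reading
frame. Trimming is ORF-anchored: the frame with the longest stop-free
downstream run is selected and the 5'-most acceptable initiation codon in
it becomes the COI start. Initiator calling covers the canonical
mitochondrial set (ATN, TTG, GTG) and the non-canonical TCG/CCG and CGA
starts, which are accepted only in the documented context: an in-frame
TAA/TAG immediately 5' of the candidate with no canonical initiator within
``initiator_scan_window_bp`` (30 bp) downstream of that stop.

Translation uses the invertebrate mitochondrial code (NCBI table 5:
AGA/AGG = Ser, TGA = Trp, ATA = Met). NUMT screening flags internal stop
codons and frameshift-sized gaps against a reference; indel detection
reports amino-acid deletions/insertions in reference coordinates counted
from the initiation codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Data import CodonTable

from .iupac import expansions, validate
from .records import Thresholds

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]
_CODON_AA = dict(_TABLE5.forward_table)
for _stop in _TABLE5.stop_codons:
    _CODON_AA[_stop] = "*"

CANONICAL_INITIATORS = {"ATA", "ATT", "ATC", "ATG", "TTG", "GTG"}
_ATN = {"ATA", "ATT", "ATC", "ATG"}
#: quadruplet starts occasionally proposed for COI; annotated, never called
QUADRUPLET_INITIATORS = {"ATAA", "TTAA", "TTAG", "ATTA"}


@lru_cache(maxsize=4096)
def _translate_codon(codon: str) -> str:
    products = {_CODON_AA[c] for c in expansions(codon)}
    return products.pop() if len(products) == 1 else "X"


def translate_mito(dna: str, frame: int = 0) -> str:
    """Translate under the invertebrate mitochondrial code (table 5).

    The trailing partial codon is dropped; stops render as '*'; a
    degenerate codon whose expansions disagree renders as 'X'.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    seq = validate(dna)[frame:]
    if len(seq) < 3:
        raise ValueError("nothing to translate after frame offset")
    return "".join(
        _translate_codon(seq[i : i + 3]) for i in range(0, len(seq) - len(seq) % 3, 3)
    )


# ---------------------------------------------------------------------------
# initiation-codon calling


def _has_canonical_within(seq: str, start: int, window_bp: int) -> bool:
    """Any canonical initiator at an in-frame codon within window_bp of start?"""
    for p in range(start, min(start + window_bp, len(seq) - 2), 3):
        if seq[p : p + 3] in CANONICAL_INITIATORS:
            return True
    return False


def call_initiation_codon(
    sequence: str,
    offset: int = 0,
    thresholds: Thresholds = Thresholds(),
) -> str:
    """Classify the codon at ``offset`` as a translation-initiation signal.

    ``sequence`` is the untrimmed read; the upstream context matters for
    the non-canonical rules. Returns one of ``ATN``, ``TTG``, ``GTG``,
    ``TCG_type``, ``CGA_type`` or ``uncertain``. TCG (or CCG) and CGA are
    accepted only when the in-frame codon immediately 5' is TAA/TAG and no
    canonical initiator occurs within ``initiator_scan_window_bp`` measured
    from the first base after that stop.
    """
    sequence = validate(sequence)
    if len(sequence) - offset < 3:
        raise ValueError("sequence shorter than one codon at offset")
    codon = sequence[offset : offset + 3]
    if codon in _ATN:
        return "ATN"
    if codon == "TTG":
        return "TTG"
    if codon == "GTG":
        return "GTG"
    if codon in {"TCG", "CCG", "CGA"}:
        has_stop_5prime = (
            offset >= 3 and sequence[offset - 3 : offset] in {"TAA", "TAG"}
        )
        if has_stop_5prime and not _has_canonical_within(
            sequence, offset, thresholds.initiator_scan_window_bp
        ):
            return "TCG_type" if codon in {"TCG", "CCG"} else "CGA_type"
    return "uncertain"


def annotate_quadruplet(sequence: str, offset: int = 0) -> str | None:
    """Report (never call) a putative quadruplet initiator at ``offset``."""
    quad = sequence[offset : offset + 4].upper()
    return quad if quad in QUADRUPLET_INITIATORS else None


# ---------------------------------------------------------------------------
# trimming


@dataclass
class TrimResult:
    coi_start: int
    trimmed: str
    initiation_call: str


class UntrimmableError(ValueError):
    """No reading frame offers a stop-free downstream ORF of >= 150 nt."""


def _stop_free_run(seq: str, p: int) -> int:
    """Nucleotides from p to the first in-frame stop (or full-codon end)."""
    q = p
    while q + 3 <= len(seq):
        if _CODON_AA.get(seq[q : q + 3]) == "*":
            break
        q += 3
    return q - p


def trim_upstream(
    read: str, thresholds: Thresholds = Thresholds()
) -> TrimResult:
    """Locate the COI initiation codon and excise the upstream tRNA filler.

    Candidate start positions are codon offsets within the first
    ``trim_band_bp[1] + 30`` bases (any frame) whose downstream stop-free
    run reaches at least 150 nt. Scanning 5'->3', the first candidate whose
    initiation call is not ``uncertain`` wins — canonical calls succeed
    directly, and the non-canonical context rule itself defers to a
    canonical start within the 30 bp scan window. If no candidate is
    acceptable, the start of the longest stop-free run is returned with an
    ``uncertain`` call.
    """
    read = validate(read)
    if len(read) < 300:
        raise ValueError("read shorter than 300 nt")
    limit = thresholds.trim_band_bp[1] + 30
    min_orf = 150

    runs = {p: _stop_free_run(read, p) for p in range(0, limit + 1)}
    best_run_start = max(runs, key=lambda p: (runs[p], -p))
    if runs[best_run_start] < min_orf:
        raise UntrimmableError(
            f"no stop-free downstream ORF of >= {min_orf} nt in any frame"
        )
    for p in sorted(runs):
        if runs[p] < min_orf:
            continue
        call = call_initiation_codon(read, p, thresholds)
        if call != "uncertain":
            return TrimResult(p, read[p:], call)
    return TrimResult(best_run_start, read[best_run_start:], "uncertain")


# ---------------------------------------------------------------------------
# NUMT screening and indel detection


@dataclass(frozen=True)
class IndelEvent:
    aa_position: int  # 1-based, reference coordinates from the initiator
    length_aa: int
    kind: str  # 'deletion' or 'insertion'

    def __post_init__(self):
        if self.aa_position < 1 or self.length_aa < 1:
            raise ValueError("aa_position and length_aa must be >= 1")


def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    # gap cost is 2 per residue; the epsilon on opening makes one contiguous
    # run beat an equal-cost split, so indel events stay contiguous
    a.open_gap_score = -2 - 1e-6
    a.extend_gap_score = -2
    # reads are 3'-truncated relative to the reference: right end gaps free
    a.right_insertion_score = 0
    a.right_deletion_score = 0
    return a


def detect_indels(
    query_protein: str, reference_protein: str, min_identity: float = 0.5
) -> list[IndelEvent]:
    """Indels of the query relative to a same-gene reference profile.

    Global alignment (match +1, mismatch -1, gap -2; the shorter 3' tail is
    not penalized). Contiguous reference-only runs are deletions, reported
    at the 1-based reference position of the first deleted residue;
    query-only runs are insertions, reported at the reference position
    immediately following the insertion point. Raises when alignment
    identity over paired columns drops below ``min_identity``.
    """
    if len(query_protein) < 50 or len(reference_protein) < 50:
        raise ValueError("proteins must be at least 50 residues")
    aln = _protein_aligner().align(reference_protein, query_protein)[0]
    ref_blocks, qry_blocks = aln.aligned
    paired = matches = 0
    for (rs, re_), (qs, _) in zip(ref_blocks, qry_blocks):
        for k in range(re_ - rs):
            paired += 1
            if reference_protein[rs + k] == query_protein[qs + k]:
                matches += 1
    if paired == 0 or matches / paired < min_identity:
        raise ValueError(
            f"alignment identity {matches}/{paired} below {min_identity:.0%}; "
            "wrong gene or frame?"
        )
    events: list[IndelEvent] = []
    for k in range(1, len(ref_blocks)):
        ref_gap = ref_blocks[k][0] - ref_blocks[k - 1][1]
        qry_gap = qry_blocks[k][0] - qry_blocks[k - 1][1]
        # reference advancing without the query = residues missing from the
        # query (deletion); query advancing without the reference = insertion
        if ref_gap and not qry_gap:
            events.append(
                IndelEvent(int(ref_blocks[k - 1][1]) + 1, int(ref_gap), "deletion")
            )
        elif qry_gap and not ref_gap:
            events.append(
                IndelEvent(int(ref_blocks[k - 1][1]) + 1, int(qry_gap), "insertion")
            )
        elif ref_gap and qry_gap:  # double gap: report both sides
            events.append(
                IndelEvent(int(ref_blocks[k - 1][1]) + 1, int(ref_gap), "deletion")
            )
            events.append(
                IndelEvent(int(ref_blocks[k - 1][1]) + 1, int(qry_gap), "insertion")
            )
    return events


def _dna_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    a.right_insertion_score = 0
    a.right_deletion_score = 0
    return a


def numt_screen(
    trimmed: str,
    protein: str,
    thresholds: Thresholds = Thresholds(),
    reference_dna: str | None = None,
) -> set[str]:
    """NUMT-signature flags for a trimmed, initiation-called read.

    INTERNAL_STOP: a stop before the final codon of the translation.
    FRAMESHIFT: nucleotide alignment against the reference coding sequence
    requires an interior gap whose length is not a multiple of 3 (needs
    ``reference_dna``). SHORT: trimmed length below the barcode floor.
    """
    flags: set[str] = set()
    if "*" in protein[:-1]:
        flags.add("INTERNAL_STOP")
    if len(trimmed) < thresholds.barcode_min_len_bp:
        flags.add("SHORT")
    if reference_dna is not None:
        aln = _dna_aligner().align(validate(reference_dna), validate(trimmed))[0]
        ref_blocks, qry_blocks = aln.aligned
        for k in range(1, len(ref_blocks)):
            gap = (ref_blocks[k][0] - ref_blocks[k - 1][1]) - (
                qry_blocks[k][0] - qry_blocks[k - 1][1]
            )
            if gap % 3 != 0:
                flags.add("FRAMESHIFT")
    return flags


# ---------------------------------------------------------------------------
# whole-read QC


@dataclass
class BarcodeRead:
    """A QC'd COI barcode read."""

    raw: str
    coi_start: int
    initiation_call: str
    protein: str
    flags: set[str]
    barcode_compliant: bool
    indels: list[IndelEvent] = field(default_factory=list)

    @property
    def trimmed(self) -> str:
        return self.raw[self.coi_start :]


def qc_read(
    raw: str,
    thresholds: Thresholds = Thresholds(),
    reference_protein: str | None = None,
    reference_dna: str | None = None,
) -> BarcodeRead:
    """Run the full QC chain: trim, call initiation, translate, screen.

    Indel detection runs when a reference protein is supplied; frameshift
    screening when a reference coding sequence is supplied. A read is
    barcode-compliant when it reaches the length floor and carries no NUMT
    flag other than SHORT.
    """
    trim = trim_upstream(raw, thresholds)
    protein = translate_mito(trim.trimmed)
    flags = numt_screen(trim.trimmed, protein, thresholds, reference_dna)
    indels: list[IndelEvent] = []
    if reference_protein is not None:
        coding = protein.split("*")[0] if "*" in protein else protein
        if len(coding) >= 50:
            try:
                indels = detect_indels(coding, reference_protein)
            except ValueError:
                # likely a mis-trimmed read or the wrong reference
                flags.add("REFERENCE_MISMATCH")
    compliant = (len(trim.trimmed) >= thresholds.barcode_min_len_bp) and not (
        flags - {"SHORT"}
    )
    return BarcodeRead(
        raw=validate(raw),
        coi_start=trim.coi_start,
        initiation_call=trim.initiation_call,
        protein=protein,
        flags=flags,
        barcode_compliant=compliant,
        indels=indels,
    )
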