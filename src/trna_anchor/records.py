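"""Annotated mitogenome records and file I/O.

Internal coordinates are 0-based half-open throughout; GenBank's 1-based
inclusive convention is converted at the parse boundary (Biopython already
does this). Origin-spanning features on circular genomes are rejected: the
region of interest is a short linear window upstream of the target gene.

Gene tokens are normalized through a data-driven synonym table
(``data/synonyms.tsv``) so that e.g. ``COX1``/``CO1``/``COI`` collapse to
``COI`` and ``tRNA-Trp`` to ``trnW``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.SeqFeature import CompoundLocation

from .iupac import IUPACError, reverse_complement, validate

GENOME_ALPHABET = set("ACGTN")


class ParseError(ValueError):
    """Malformed input file; the message names the offending line or record."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GeneFeature:
    """A named, stranded gene interval (0-based half-open)."""

    name: str
    start: int
    end: int
    strand: int  # +1 or -1

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.name}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in (1, -1):
            raise ValueError(f"feature {self.name}: strand must be +1 or -1")

    @property
    def length(self) -> int:
        return self.end - self.start

    def three_prime(self) -> int:
        """Coordinate of the strand-aware 3' edge (half-open end for +,
        start for -)."""
        return self.end if self.strand == 1 else self.start


@dataclass
class MitoGenome:
    """An annotated (conceptually circular) mitochondrial DNA record."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"genome {self.id}: empty sequence")
        bad = set(self.sequence) - GENOME_ALPHABET
        if bad:
            raise ValueError(
                f"genome {self.id}: characters outside A/C/G/T/N: {sorted(bad)}"
            )
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise ValueError(
                    f"genome {self.id}: feature {f.name} [{f.start}, {f.end}) "
                    f"outside sequence of length {n}"
                )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.name))

    def __len__(self) -> int:
        return len(self.sequence)

    def features_named(self, token: str) -> list[GeneFeature]:
        return [f for f in self.features if f.name == token]

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Strand-corrected (5'->3') sequence of a feature."""
        s = self.sequence[feat.start : feat.end]
        return s if feat.strand == 1 else reverse_complement(s)

    def reverse_complemented(self) -> "MitoGenome":
        """The same record on the opposite strand, features remapped."""
        n = len(self.sequence)
        feats = [
            GeneFeature(f.name, n - f.end, n - f.start, -f.strand)
            for f in self.features
        ]
        return MitoGenome(self.id, reverse_complement(self.sequence), self.circular, feats)


@dataclass(frozen=True)
class Thresholds:
    """Tunable cutoffs used across the survey / in-silico PCR / QC stages.

    Defaults encode the study conditions: a 200 bp anchor window, 60-68 bp
    tRNAs, failure when the 3'-weighted mismatch score exceeds 3 with a 10 nt
    3' window, a 30 bp scan window for the non-canonical initiator rule,
    a 500 bp barcode-compliance floor, a 70-200 bp upstream trim band and a
    730-870 bp amplicon band.
    """

    max_anchor_distance_bp: int = 200
    trna_len_range: tuple[int, int] = (60, 68)
    mismatch_fail_count: int = 3
    three_prime_window_nt: int = 10
    initiator_scan_window_bp: int = 30
    barcode_min_len_bp: int = 500
    trim_band_bp: tuple[int, int] = (70, 200)
    amplicon_band_bp: tuple[int, int] = (730, 870)

    def __post_init__(self):
        scalars = (
            self.max_anchor_distance_bp,
            self.mismatch_fail_count,
            self.three_prime_window_nt,
            self.initiator_scan_window_bp,
            self.barcode_min_len_bp,
        )
        if any(v <= 0 for v in scalars):
            raise ValueError("all threshold values must be positive")
        for lo, hi in (
            self.trna_len_range,
            self.trim_band_bp,
            self.amplicon_band_bp,
        ):
            if not (0 < lo <= hi):
                raise ValueError(f"invalid band ({lo}, {hi})")


# ---------------------------------------------------------------------------
# gene-token normalization


def load_synonyms(path: str | Path | None = None) -> dict[str, str]:
    """Load the alias -> canonical-token map (tab-separated, header row)."""
    if path is None:
        text = (
            resources.files("trna_anchor").joinpath("data/synonyms.tsv").read_text()
        )
    else:
        text = Path(path).read_text()
    table: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "alias":
            continue
        if len(parts) != 2:
            raise ParseError(f"synonyms line {lineno}: expected 2 columns")
        table[parts[0].strip().upper()] = parts[1].strip()
    return table


_DEFAULT_SYNONYMS: dict[str, str] | None = None


def normalize_token(name: str, synonyms: dict[str, str] | None = None) -> str:
    """Map a raw gene name to its canonical token (idempotent)."""
    global _DEFAULT_SYNONYMS
    if synonyms is None:
        if _DEFAULT_SYNONYMS is None:
            _DEFAULT_SYNONYMS = load_synonyms()
        synonyms = _DEFAULT_SYNONYMS
    key = name.strip().upper()
    if key in synonyms:
        return synonyms[key]
    # canonical outputs pass through unchanged (idempotence)
    if name in set(synonyms.values()):
        return name
    return name.strip()


# ---------------------------------------------------------------------------
# GenBank / TSV annotation readers

_FEATURE_KEYS = {"gene", "tRNA", "CDS", "rRNA"}


def _genbank_record_to_genome(rec, synonyms) -> MitoGenome:
    feats: list[GeneFeature] = []
    seen: set[tuple[str, int, int]] = set()
    for f in rec.features:
        if f.type not in _FEATURE_KEYS:
            continue
        name = None
        for qual in ("gene", "product"):
            if qual in f.qualifiers:
                name = f.qualifiers[qual][0]
                break
        if name is None:
            continue
        if isinstance(f.location, CompoundLocation):
            raise ParseError(
                f"record {rec.id}: origin-spanning/compound feature {name!r} "
                "is not supported"
            )
        strand = f.location.strand
        if strand not in (1, -1):
            raise ParseError(f"record {rec.id}: feature {name!r} has unknown strand")
        token = normalize_token(name, synonyms)
        key = (token, int(f.location.start), int(f.location.end))
        if key in seen:  # gene + CDS/tRNA pairs annotate the same interval
            continue
        seen.add(key)
        feats.append(
            GeneFeature(token, int(f.location.start), int(f.location.end), strand)
        )
    seq = str(rec.seq).upper().replace("U", "T")
    circular = rec.annotations.get("topology", "circular") == "circular"
    return MitoGenome(rec.id, seq, circular, feats)


def _read_tsv_annotations(path: Path, synonyms) -> list[MitoGenome]:
    """Minimal tabular dialect: genome_id, feature_name, start, end, strand.

    Coordinates are 0-based half-open. A row whose feature_name is
    ``genome`` declares the record length in the ``end`` column; otherwise
    length is the max feature end. Sequence is filled with N (annotation-only
    records support the arrangement survey, which needs no bases).
    """
    per_genome: dict[str, list[GeneFeature]] = {}
    lengths: dict[str, int] = {}
    order: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "genome_id":
            continue
        if len(parts) != 5:
            raise ParseError(f"{path.name} line {lineno}: expected 5 columns")
        gid, name, start_s, end_s, strand_s = parts
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError(
                f"{path.name} line {lineno}: malformed coordinates "
                f"{start_s!r}/{end_s!r}"
            ) from None
        if gid not in per_genome:
            per_genome[gid] = []
            order.append(gid)
        if name == "genome":
            lengths[gid] = end
            continue
        strand_map = {"+": 1, "-": -1, "+1": 1, "-1": -1, "1": 1}
        if strand_s not in strand_map:
            raise ParseError(
                f"{path.name} line {lineno}: unknown strand symbol {strand_s!r}"
            )
        if end <= start:
            raise ParseError(
                f"{path.name} line {lineno}: feature end {end} <= start {start}"
            )
        per_genome[gid].append(
            GeneFeature(normalize_token(name, synonyms), start, end, strand_map[strand_s])
        )
    genomes = []
    for gid in order:
        feats = per_genome[gid]
        n = lengths.get(gid, max((f.end for f in feats), default=1))
        genomes.append(MitoGenome(gid, "N" * n, True, feats))
    return genomes


def read_genbank_subset(
    path: str | Path, synonyms: dict[str, str] | None = None
) -> list[MitoGenome]:
    """Read annotated genomes from a GenBank flat file or the TSV dialect.

    Format is chosen by extension (.gb/.gbk/.genbank vs .tsv) with a content
    sniff fallback (GenBank files start with ``LOCUS``).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".tsv", ".txt"}:
        return _read_tsv_annotations(path, synonyms)
    if suffix not in {".gb", ".gbk", ".genbank"}:
        head = path.read_text()[:5]
        if not head.startswith("LOCUS"):
            return _read_tsv_annotations(path, synonyms)
    try:
        recs = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ParseError(f"{path.name}: {exc}") from exc
    return [_genbank_record_to_genome(r, synonyms) for r in recs]


def write_tsv_annotations(genomes: Iterable[MitoGenome], path: str | Path) -> None:
    lines = ["genome_id\tfeature_name\tstart\tend\tstrand"]
    for g in genomes:
        lines.append(f"{g.id}\tgenome\t0\t{len(g)}\t+")
        for f in g.features:
            lines.append(
                f"{g.id}\t{f.name}\t{f.start}\t{f.end}\t{'+' if f.strand == 1 else '-'}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (id, upper-case sequence) pairs.

    Raises on an empty sequence or a character outside the IUPAC DNA
    alphabet (position named in the error).
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ParseError(f"record {rec.id}: empty sequence")
        try:
            seq = validate(seq)
        except IUPACError as exc:
            raise ParseError(f"record {rec.id}: {exc}") from exc
        out.append((rec.id, seq))
    return out


def write_fasta(
    records: Sequence[tuple[str, str]], path: str | Path, wrap: int = 70
) -> None:
    """Write (id, sequence) pairs as FASTA with a configurable wrap width."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")
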