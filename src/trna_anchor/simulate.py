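"""Seeded synthetic mitogenomes, amplicons and reads with truth records.

The generator emulates the structure of surveyed hexapod mitogenomes at
the COI locus: an upstream run of 60-68 bp tRNA genes in one of the
observed arrangements (``W,-C,-Y`` dominant), a tRNA-W gene carrying one of
the two conserved anchor blocks (drawn uniformly from the expansions of the
group consensus), short intergenic gaps, and a COI gene built by
back-translating a fixed 230-residue reference protein with uniform
synonymous codon choice. Initiation codons, amino-acid deletions and
binding-site substitutions are planted per configuration and recorded in a
truth record, so every analysis operation can be scored against ground
truth without any external download.

Everything is a pure function of (config.seed, index): the same pair
always yields byte-identical records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus import GROUP1_CONSENSUS, GROUP2_CONSENSUS
from .iupac import bases, reverse_complement
from .qc import CANONICAL_INITIATORS, _CODON_AA, _stop_free_run, call_initiation_codon
from .records import GeneFeature, MitoGenome

_BASES = np.array(list("ACGT"))

# amino acid -> codons, invertebrate mitochondrial code
_AA_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODON_AA.items()):
    if _aa != "*":
        _AA_CODONS.setdefault(_aa, []).append(_codon)

_REF_LEN = 230
#: protein positions (1-based) where back-translation avoids codons that
#: double as canonical initiators, keeping the 30 bp scan window clean for
#: the non-canonical initiator rule
_INITIATOR_WINDOW_RESIDUES = range(2, 11)
#: residues whose codons are pinned so every genome shares the standard
#: forward / reverse primer binding sites
_FIXED_FWD_RESIDUES = range(9, 18)
_FIXED_REV_RESIDUES = range(222, 231)

FWD_BINDING_WINDOW = (24, 50)  # nt in COI coordinates, 26 nt wide
REV_BINDING_WINDOW = (663, 689)


def _make_reference_protein() -> str:
    rng = np.random.default_rng(20100709)
    aas = sorted(set(_AA_CODONS) - {"X"})
    protein = ["M"]
    for pos in range(2, _REF_LEN + 1):
        choices = [a for a in aas if not (pos in _INITIATOR_WINDOW_RESIDUES and a == "M")]
        protein.append(choices[rng.integers(len(choices))])
    return "".join(protein)


REFERENCE_PROTEIN = _make_reference_protein()


def _codon_choices(aa: str, pos: int) -> list[str]:
    codons = _AA_CODONS[aa]
    if pos in _INITIATOR_WINDOW_RESIDUES:
        safe = [c for c in codons if c not in CANONICAL_INITIATORS]
        if safe:
            codons = safe
    return codons


def _fixed_codon(aa: str, pos: int) -> str:
    return _codon_choices(aa, pos)[0]


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous back-translation with the pinned binding-site and
    initiator-window codon constraints applied."""
    out = []
    for i, aa in enumerate(protein):
        pos = i + 1
        if pos in _FIXED_FWD_RESIDUES or pos in _FIXED_REV_RESIDUES:
            out.append(_fixed_codon(aa, pos))
        else:
            choices = _codon_choices(aa, pos)
            out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _reference_fixed_dna() -> str:
    """Reference coding DNA with every codon at its pinned/first choice —
    the profile from which the synthetic standard primer sites are read."""
    return "".join(
        _fixed_codon(aa, i + 1) for i, aa in enumerate(REFERENCE_PROTEIN)
    )


_REF_FIXED_DNA = _reference_fixed_dna()
#: synthetic stand-ins for the standard universal barcode primers (their
#: real sequences are configuration inputs, never baked in)
STANDARD_FWD_SITE = _REF_FIXED_DNA[FWD_BINDING_WINDOW[0] : FWD_BINDING_WINDOW[1]]
STANDARD_REV_SITE = _REF_FIXED_DNA[REV_BINDING_WINDOW[0] : REV_BINDING_WINDOW[1]]


@dataclass
class SimConfig:
    """Study conditions for the synthetic corpus.

    Defaults mirror the surveyed hexapod proportions: 126 genomes, 120 of
    them with a forward tRNA-W upstream of COI, anchor groups split 92/28,
    tRNAs of 60-68 bp, intergenic gaps of 0-20 bp, and initiator classes
    at the observed frequencies. ``exact_mix`` converts weights into exact
    (largest-remainder) counts assigned by a seeded permutation.
    """

    seed: int = 0
    n_genomes: int = 126
    arrangement_mix: tuple[tuple[str, float], ...] = (
        ("W,-C,-Y", 100),
        ("W,-Y", 8),
        ("W,-C", 6),
        ("W", 6),
        ("", 6),
    )
    group_mix: tuple[float, float] = (92, 28)
    exact_mix: bool = True
    trna_len_range: tuple[int, int] = (60, 68)
    intergenic_gap_range: tuple[int, int] = (0, 20)
    coi_initiator: str | dict[str, float] = field(
        default_factory=lambda: {
            "ATN": 58, "TTG": 14, "GTG": 1, "TCG": 21, "CCG": 1, "CGA": 17,
        }
    )
    planted_indels: tuple[tuple[int, int], ...] = ()
    planted_primer_mismatches: tuple[tuple[int, str], ...] = ()
    filler_band: tuple[int, int] = (70, 200)
    amplicon_band: tuple[int, int] = (730, 870)
    reject_confounders: bool = False
    anchor_offset: int = 20

    def __post_init__(self):
        if not self.arrangement_mix or all(w <= 0 for _, w in self.arrangement_mix):
            raise ValueError("arrangement_mix needs at least one positive weight")
        if any(w < 0 for _, w in self.arrangement_mix):
            raise ValueError("arrangement weights must be non-negative")
        for lo, hi in (self.trna_len_range, self.filler_band, self.amplicon_band):
            if lo > hi:
                raise ValueError(f"band ({lo}, {hi}) inverted")
        if self.filler_band[1] + 500 > self.amplicon_band[1] + 200:
            raise ValueError("filler and amplicon bands are inconsistent")


@dataclass
class GenomeTruth:
    """Everything planted into one synthetic genome."""

    genome_id: str
    arrangement: str
    group: int | None  # 1, 2 or None when no anchor
    anchor_span: tuple[int, int] | None
    anchor_seq: str | None
    anchor_distance: int | None
    coi_start: int
    coi_end: int
    initiator_class: str | None
    initiator_codon: str | None
    protein: str
    coding_dna: str
    planted_indels: tuple[tuple[int, int], ...]
    planted_mismatches: tuple[tuple[int, str], ...]
    confounded: bool = False


@dataclass
class ReadTruth:
    genome_id: str
    coi_start: int  # offset of the initiation codon within the read
    initiator_class: str | None
    initiator_codon: str | None
    length: int


def _largest_remainder(weights: list[float], n: int) -> list[int]:
    total = sum(weights)
    quotas = [w / total * n for w in weights]
    counts = [int(q) for q in quotas]
    for i in sorted(
        range(len(weights)), key=lambda i: (counts[i] - quotas[i], i)
    )[: n - sum(counts)]:
        counts[i] += 1
    return counts


def _assignments(config: SimConfig) -> list[tuple[str, int | None]]:
    """Per-index (arrangement pattern, anchor group) assignment."""
    rng = np.random.default_rng([config.seed, 777])
    patterns = [p for p, _ in config.arrangement_mix]
    weights = np.array([w for _, w in config.arrangement_mix], dtype=float)
    n = config.n_genomes
    if config.exact_mix:
        counts = _largest_remainder(list(weights), n)
        pool = [p for p, c in zip(patterns, counts) for _ in range(c)]
        order = rng.permutation(n)
        arr = [pool[i] for i in order]
    else:
        arr = [
            patterns[i]
            for i in rng.choice(len(patterns), size=n, p=weights / weights.sum())
        ]
    anchored = [i for i, p in enumerate(arr) if "W" in p.replace("-W", "")]
    gw = np.array(config.group_mix, dtype=float)
    if config.exact_mix:
        counts = _largest_remainder(list(gw), len(anchored))
        gpool = [1] * counts[0] + [2] * counts[1]
        gorder = rng.permutation(len(anchored))
        groups_for_anchored = [gpool[i] for i in gorder]
    else:
        groups_for_anchored = [
            int(g) + 1
            for g in rng.choice(2, size=len(anchored), p=gw / gw.sum())
        ]
    groups: list[int | None] = [None] * n
    for i, g in zip(anchored, groups_for_anchored):
        groups[i] = g
    return list(zip(arr, groups))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _expand_uniform(consensus: str, rng: np.random.Generator) -> str:
    return "".join(
        sorted(bases(c))[rng.integers(len(bases(c)))] for c in consensus
    )


def _pick_initiator(config: SimConfig, rng: np.random.Generator) -> tuple[str, str]:
    """Return (class, concrete codon)."""
    spec = config.coi_initiator
    if isinstance(spec, str):
        cls = spec
    else:
        keys = sorted(spec)
        w = np.array([spec[k] for k in keys], dtype=float)
        cls = keys[rng.choice(len(keys), p=w / w.sum())]
    if cls == "ATN":
        return "ATN", ["ATA", "ATT", "ATC", "ATG"][rng.integers(4)]
    if cls in {"TTG", "GTG", "TCG", "CCG", "CGA"}:
        return cls, cls
    raise ValueError(f"unknown initiator class {cls!r}")


def _coi_coding(
    config: SimConfig, rng: np.random.Generator
) -> tuple[str, str, str, str]:
    """Build (coding_dna_with_stop, protein, initiator_class, codon)."""
    protein = REFERENCE_PROTEIN
    for pos, length in sorted(config.planted_indels, reverse=True):
        protein = protein[: pos - 1] + protein[pos - 1 + length :]
    cls, codon = _pick_initiator(config, rng)
    dna = back_translate(protein, rng)
    dna = codon + dna[3:]
    for pos, base in config.planted_primer_mismatches:
        site = FWD_BINDING_WINDOW[0] + pos
        dna = dna[:site] + base + dna[site + 1 :]
    stop = ["TAA", "TAG"][rng.integers(2)]
    return dna + stop, protein, cls, codon


def _upstream_confounded(seq: str, coi_start: int) -> bool:
    lo = max(0, coi_start - 200)
    for p in range(lo, coi_start):
        if _stop_free_run(seq, p) < 150:
            continue
        if call_initiation_codon(seq, p) != "uncertain":
            return True
    return False


def generate_mitogenome(
    config: SimConfig, index: int
) -> tuple[MitoGenome, GenomeTruth]:
    """One synthetic genome plus its truth record (deterministic)."""
    pattern, group = _assignments(config)[index]
    rng = np.random.default_rng([config.seed, index])
    coding, protein, init_cls, init_codon = _coi_coding(config, rng)
    g_lo, g_hi = config.intergenic_gap_range
    t_lo, t_hi = config.trna_len_range
    needs_stop_context = init_cls in {"TCG", "CCG", "CGA"}

    tokens = []
    if pattern:
        for piece in pattern.split(","):
            sign = -1 if piece.startswith("-") else 1
            tokens.append((f"trn{piece.lstrip('-')}", sign))

    for attempt in range(500):
        pad = _random_dna(rng, int(rng.integers(210, 261)))
        parts = [pad]
        feats: list[tuple[str, int, int, int]] = []  # name, start, end, strand
        anchor_span = anchor_seq = None
        pos = len(pad)
        for name, sign in tokens:
            tlen = int(rng.integers(t_lo, t_hi + 1))
            if name == "trnW" and group is not None:
                cons = GROUP1_CONSENSUS if group == 1 else GROUP2_CONSENSUS
                block = _expand_uniform(cons, rng)
                off = config.anchor_offset
                gene = _random_dna(rng, off) + block + "A"
                gene += _random_dna(rng, tlen - len(gene))
                anchor_seq = block
                if sign == 1:
                    anchor_span = (pos + off, pos + off + len(block))
                    parts.append(gene)
                else:
                    anchor_span = (
                        pos + tlen - off - len(block),
                        pos + tlen - off,
                    )
                    parts.append(reverse_complement(gene))
            else:
                gene = _random_dna(rng, tlen)
                parts.append(gene if sign == 1 else reverse_complement(gene))
            feats.append((name, pos, pos + tlen, sign))
            pos += tlen
            gap = int(rng.integers(g_lo, g_hi + 1))
            parts.append(_random_dna(rng, gap))
            pos += gap
        if needs_stop_context:
            # in-frame TAA/TAG directly 5' of the initiator
            stop = ["TAA", "TAG"][rng.integers(2)]
            parts.append(stop)
            pos += 3
        coi_start = pos
        parts.append(coding)
        pos += len(coding)
        feats.append(("COI", coi_start, coi_start + len(coding) - 3, 1))
        parts.append(_random_dna(rng, int(rng.integers(80, 141))))
        seq = "".join(parts)
        if not config.reject_confounders or not _upstream_confounded(seq, coi_start):
            confounded = False
            break
    else:
        confounded = True

    features = [GeneFeature(n, s, e, st) for n, s, e, st in feats]
    genome = MitoGenome(f"synth{index:04d}", seq, True, features)
    w_feats = [f for f in features if f.name == "trnW"]
    distance = coi_start - w_feats[0].three_prime() if w_feats else None
    truth = GenomeTruth(
        genome_id=genome.id,
        arrangement=pattern,
        group=group,
        anchor_span=anchor_span,
        anchor_seq=anchor_seq,
        anchor_distance=distance,
        coi_start=coi_start,
        coi_end=coi_start + len(coding) - 3,
        initiator_class=init_cls,
        initiator_codon=init_codon,
        protein=protein,
        coding_dna=coding[:-3],
        planted_indels=tuple(config.planted_indels),
        planted_mismatches=tuple(config.planted_primer_mismatches),
        confounded=confounded,
    )
    return genome, truth


def generate_corpus(config: SimConfig) -> list[tuple[MitoGenome, GenomeTruth]]:
    return [generate_mitogenome(config, i) for i in range(config.n_genomes)]


def generate_read(
    genome: MitoGenome,
    truth: GenomeTruth,
    config: SimConfig,
    index: int = 0,
    predicted_success: bool | None = None,
) -> tuple[str, ReadTruth]:
    """One sequencer read: tRNA-derived filler + the 5' COI segment.

    The filler length falls in ``filler_band`` and the total length in
    ``amplicon_band``. When the caller has run an amplification prediction,
    pass its outcome: a predicted failure raises, since no read would exist.
    """
    if predicted_success is False:
        raise ValueError(
            f"{genome.id}: primer pair predicted to fail; no read to generate"
        )
    rng = np.random.default_rng([config.seed, 100_000 + index])
    f_lo, f_hi = config.filler_band
    a_lo, a_hi = config.amplicon_band
    f_hi = min(f_hi, truth.coi_start)
    if f_hi < f_lo:
        raise ValueError(f"{genome.id}: not enough upstream sequence for filler")
    filler_len = int(rng.integers(f_lo, f_hi + 1))
    coi_avail = len(truth.coding_dna) + 3
    t_lo = max(a_lo, filler_len + 500)
    t_hi = min(a_hi, filler_len + coi_avail)
    if t_lo > t_hi:
        raise ValueError(f"{genome.id}: amplicon band unreachable")
    total = int(rng.integers(t_lo, t_hi + 1))
    start = truth.coi_start - filler_len
    read = genome.sequence[start : start + total]
    return read, ReadTruth(
        genome_id=genome.id,
        coi_start=filler_len,
        initiator_class=truth.initiator_class,
        initiator_codon=truth.initiator_codon,
        length=total,
    )
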