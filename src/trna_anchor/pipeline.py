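"""Configuration, report writing and the end-to-end pipeline.

Stages: survey (arrangement tabulation + anchor ranking) -> cluster
(anchor-gene alignment and homogeneity grouping) -> design (degenerate
primers from group consensi) -> ispcr (per-template amplification
prediction) -> qc (read trimming, initiation calling, NUMT screen).
Every stage writes one tab-separated report (no quoting, header row) with
a JSON run manifest alongside; a stage failure aborts the run, naming the
stage and input, and leaves any in-progress report behind with a
``.partial`` suffix.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .arrangement import select_anchor, tabulate_arrangements
from .consensus import (
    M13_TAIL,
    PrimerSpec,
    center_star_msa,
    design_primer,
    partition_groups,
    primer_tm,
)
from .ispcr import best_footprint, predict_amplification, scan_primer
from .qc import qc_read
from .records import MitoGenome, Thresholds

log = logging.getLogger("trna_anchor")

_KNOWN_KEYS = {
    "thresholds",
    "primers",
    "synonyms",
    "out_dir",
    "log_level",
    "seed",
    "survey",
    "cluster",
    "design",
}


@dataclass
class RunConfig:
    thresholds: Thresholds = field(default_factory=Thresholds)
    primers: list[dict] = field(default_factory=list)
    synonyms: str | None = None
    out_dir: str = "."
    log_level: str = "INFO"
    seed: int = 0
    target: str = "COI"
    window_bp: int = 200
    identity_threshold: float = 0.75
    min_freq: float = 0.05
    cluster_window: tuple[int, int] | None = None
    anchor_slice: tuple[int, int] | None = None  # (offset, width) on gene seqs
    design_tail: str | None = M13_TAIL

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kw: dict = {}
        if "thresholds" in raw:
            kw["thresholds"] = Thresholds(**raw["thresholds"])
        for key in ("primers", "synonyms", "out_dir", "log_level", "seed"):
            if key in raw:
                kw[key] = raw[key]
        survey = raw.get("survey", {})
        kw["target"] = survey.get("target", "COI")
        kw["window_bp"] = survey.get("window_bp", 200)
        cluster = raw.get("cluster", {})
        kw["identity_threshold"] = cluster.get("identity_threshold", 0.75)
        kw["min_freq"] = cluster.get("min_freq", 0.05)
        if "window" in cluster:
            kw["cluster_window"] = tuple(cluster["window"])
        if "anchor_slice" in cluster:
            kw["anchor_slice"] = tuple(cluster["anchor_slice"])
        design = raw.get("design", {})
        if "tail" in design:
            kw["design_tail"] = design["tail"] or None
        cfg = cls(**kw)
        if cfg.synonyms and not Path(cfg.synonyms).exists():
            raise FileNotFoundError(f"synonyms file not found: {cfg.synonyms}")
        return cfg


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {detail}")


def primers_from_config(config: RunConfig) -> list[PrimerSpec]:
    return [
        PrimerSpec(
            name=p["name"],
            core=p["core"],
            tail=p.get("tail"),
            direction=p.get("direction", "forward"),
        )
        for p in config.primers
    ]


def load_primers_tsv(path: str | Path) -> list[PrimerSpec]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        PrimerSpec(
            name=r["name"],
            core=r["core"],
            tail=r["tail"] or None,
            direction=r.get("direction", "forward") or "forward",
        )
        for r in df.to_dict("records")
    ]


def write_tsv(df: pd.DataFrame, path: Path) -> None:
    """Canonical report format: tab-separated, header row, no quoting."""
    partial = path.with_suffix(path.suffix + ".partial")
    df.to_csv(partial, sep="\t", index=False)
    partial.rename(path)


def primer_table(primers: list[PrimerSpec]) -> pd.DataFrame:
    rows = []
    for p in primers:
        tmin, tmax = primer_tm(p) if len(p.core) >= 10 else (float("nan"),) * 2
        rows.append(
            {
                "name": p.name,
                "core": p.core,
                "tail": p.tail or "",
                "direction": p.direction,
                "degeneracy": p.degeneracy,
                "tm_min": tmin,
                "tm_max": tmax,
            }
        )
    return pd.DataFrame(rows)


def _predict_for_template(
    fwd: PrimerSpec, rev: PrimerSpec, tid: str, seq: str, thresholds: Thresholds
) -> dict:
    try:
        fhit = best_footprint(fwd, seq, strand="+")
        if fhit.mismatch_count > len(fwd.core) // 2:
            fhit = None
    except ValueError:
        fhit = None
    try:
        rhit = best_footprint(rev, seq, strand="-")
        if rhit.mismatch_count > len(rev.core) // 2:
            rhit = None
    except ValueError:
        rhit = None
    if fhit and rhit and rhit.footprint[0] < fhit.footprint[1]:
        rhit = None
    pred = predict_amplification(fhit, rhit, thresholds)
    return {
        "template": tid,
        "forward": fwd.name,
        "reverse": rev.name,
        "fwd_mismatches": fhit.mismatch_count if fhit else "",
        "rev_mismatches": rhit.mismatch_count if rhit else "",
        "fwd_score": fhit.weighted_score(thresholds) if fhit else "",
        "rev_score": rhit.weighted_score(thresholds) if rhit else "",
        "success": pred.success,
        "reasons": ";".join(pred.reasons),
        "amplicon_length": pred.length_bp if pred.length_bp is not None else "",
    }


def run_pipeline(
    config: RunConfig,
    genomes: list[MitoGenome],
    templates: list[tuple[str, str]],
    reference_protein: str | None = None,
) -> dict:
    """Execute survey -> cluster -> design on genomes, then ispcr -> qc on
    templates. Returns a dict of stage DataFrames; TSV reports plus a JSON
    manifest land in ``config.out_dir``."""
    if not genomes:
        raise PipelineStageError("survey", "no input genomes")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    th = config.thresholds

    # --- survey
    stage = "survey"
    try:
        tab = tabulate_arrangements(genomes, config.target, config.window_bp)
        anchors = select_anchor(tab, th)
        anchor_df = pd.DataFrame(
            [
                {
                    "gene": a.gene,
                    "presence_fraction": a.presence_fraction,
                    "forward_fraction": a.forward_fraction,
                    "median_distance": a.distance_bp,
                    "eligible": a.eligible,
                }
                for a in anchors
            ]
        )
        write_tsv(tab.arrangements, out / "survey_arrangements.tsv")
        write_tsv(tab.gene_summary, out / "survey_genes.tsv")
        write_tsv(anchor_df, out / "survey_anchors.tsv")
        results["arrangements"] = tab.arrangements
        results["anchors"] = anchor_df
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # --- cluster
    stage = "cluster"
    try:
        anchor_gene = anchors[0].gene if anchors else None
        groups = []
        if anchor_gene is not None:
            ids, seqs = [], []
            for g in genomes:
                feats = g.features_named(anchor_gene)
                if not feats:
                    continue
                s = g.feature_sequence(feats[0])
                if config.anchor_slice is not None:
                    off, width = config.anchor_slice
                    s = s[off : off + width]
                ids.append(g.id)
                seqs.append(s)
            if len(seqs) >= 2:
                block = center_star_msa(seqs, ids)
                groups = partition_groups(
                    block,
                    window=config.cluster_window,
                    identity_threshold=config.identity_threshold,
                    min_freq=config.min_freq,
                )
        group_df = pd.DataFrame(
            [
                {
                    "group": i + 1,
                    "n_members": len(grp.member_ids),
                    "consensus": grp.consensus.iupac,
                    "members": ",".join(grp.member_ids),
                }
                for i, grp in enumerate(groups)
            ]
        )
        write_tsv(group_df, out / "cluster_groups.tsv")
        results["groups"] = group_df
        results["group_objects"] = groups
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # --- design
    stage = "design"
    try:
        designed = [
            design_primer(
                grp.consensus,
                tail=config.design_tail,
                prefer_3prime_GC=True,
                name=f"anchorF{i + 1}",
            )
            for i, grp in enumerate(groups)
        ]
        configured = primers_from_config(config)
        primer_df = primer_table(designed + configured)
        write_tsv(primer_df, out / "design_primers.tsv")
        results["primers"] = primer_df
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # --- ispcr
    stage = "ispcr"
    try:
        rows = []
        amplicons: list[tuple[str, str]] = []
        if templates:
            fwds = [p for p in designed + configured if p.direction == "forward"]
            revs = [p for p in configured if p.direction == "reverse"]
            for tid, seq in templates:
                for fwd in fwds:
                    for rev in revs:
                        row = _predict_for_template(fwd, rev, tid, seq, th)
                        rows.append(row)
                        if row["success"]:
                            fhit = best_footprint(fwd, seq, strand="+")
                            rhit = best_footprint(rev, seq, strand="-")
                            amplicons.append(
                                (
                                    f"{tid}__{fwd.name}",
                                    seq[fhit.footprint[0] : rhit.footprint[1]],
                                )
                            )
        pred_df = pd.DataFrame(
            rows,
            columns=[
                "template", "forward", "reverse", "fwd_mismatches",
                "rev_mismatches", "fwd_score", "rev_score", "success",
                "reasons", "amplicon_length",
            ],
        )
        write_tsv(pred_df, out / "ispcr_predictions.tsv")
        results["predictions"] = pred_df
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # --- qc (runs on the predicted amplicons, which are the reads a
    # successful reaction would deliver)
    stage = "qc"
    try:
        qrows = []
        for tid, seq in amplicons:
            if len(seq) < 300:
                qrows.append(
                    {"id": tid, "coi_start": "", "initiation_call": "",
                     "flags": "TOO_SHORT_TO_QC", "compliant": False,
                     "indels": ""}
                )
                continue
            br = qc_read(seq, th, reference_protein=reference_protein)
            qrows.append(
                {
                    "id": tid,
                    "coi_start": br.coi_start,
                    "initiation_call": br.initiation_call,
                    "flags": ";".join(sorted(br.flags)),
                    "compliant": br.barcode_compliant,
                    "indels": ";".join(
                        f"{e.kind}@{e.aa_position}x{e.length_aa}" for e in br.indels
                    ),
                }
            )
        qc_df = pd.DataFrame(
            qrows,
            columns=["id", "coi_start", "initiation_call", "flags",
                     "compliant", "indels"],
        )
        write_tsv(qc_df, out / "qc_reads.tsv")
        results["qc"] = qc_df
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    manifest = {
        "tool": "trna-anchor",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "n_genomes": len(genomes),
        "n_templates": len(templates),
        "target": config.target,
        "config_hash": hashlib.sha256(
            json.dumps(
                {k: str(v) for k, v in vars(config).items()}, sort_keys=True
            ).encode()
        ).hexdigest(),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    results["manifest"] = manifest
    return results
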