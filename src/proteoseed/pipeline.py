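"""End-to-end orchestration: build-db -> map -> refine -> ortho, with a YAML
config, stage caching keyed by input digests, and report generation.

Machine-readable outputs (TSV/GFF3/JSON) are kept strictly separate from the
run log, which goes to stderr.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .evidence import (
    aggregate_to_proteins,
    decoy_fdr,
    filter_psms,
    map_all_psms,
    read_psm_table,
)
from .genome_model import (
    AnnotationSet,
    CdsAnnotation,
    GenomeRecord,
    ProteoseedError,
    coords_to_length,
    extract_and_translate,
    read_annotation,
    read_genome,
    write_annotation,
)
from .ortho import find_unannotated_homologs, propagate_start_corrections
from .refinement import PipelineConfig, RefinementResult, refine_all, start_codon_usage
from .sixframe import build_search_db, enumerate_orfs, read_search_db

logger = logging.getLogger("proteoseed")

__all__ = ["RunManifest", "run_pipeline", "write_reports", "coverage_percent"]


@dataclass
class RunManifest:
    config: dict
    input_digests: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    version: str = __version__

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_config(config_path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(config_path).read_text())
    if not isinstance(cfg, dict) or "genome" not in cfg:
        raise ProteoseedError(f"{config_path}: config must at least name a genome")
    return cfg


def _thresholds(cfg: dict) -> PipelineConfig:
    fields = {k: cfg[k] for k in (
        "min_orf_aa", "min_peptides_validate", "one_hit_p_max", "psm_p_max",
        "frame_gap_max_nt", "evalue_novel", "evalue_nterm") if k in cfg}
    pc = PipelineConfig(**fields)
    for name, value in asdict_flat(pc).items():
        logger.info("threshold %s = %r", name, value)
    return pc


def asdict_flat(pc: PipelineConfig) -> dict:
    return {k: getattr(pc, k) for k in (
        "min_orf_aa", "min_peptides_validate", "one_hit_p_max", "psm_p_max",
        "canonical_starts", "frame_gap_max_nt", "evalue_novel", "evalue_nterm")}


def _read_flag_table(path: str | Path) -> dict:
    out = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:  # header skipped
        if not line.strip():
            continue
        key, _, val = line.partition("\t")
        out[key.strip()] = val.strip().lower() in ("1", "true", "yes")
    return out


def run_pipeline(config_path: str | Path) -> RunManifest:
    """Execute build-db -> map -> refine (-> ortho) as configured.

    The search-database stage is cached: when the genome digest and ORF
    length threshold recorded in the manifest match, the FASTA on disk is
    reused instead of re-enumerated.
    """
    cfg = _load_config(config_path)
    base = Path(config_path).parent
    outdir = Path(cfg.get("outdir", base / "proteoseed_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    pc = _thresholds(cfg)
    manifest = RunManifest(config=cfg)

    def path_of(key):
        p = Path(cfg[key])
        return p if p.is_absolute() else base / p

    # --- stage: search database
    t0 = time.perf_counter()
    genomes = read_genome(path_of("genome"))
    manifest.input_digests["genome"] = _digest(path_of("genome"))
    db_fa = outdir / "db.fa"
    prev = _previous_manifest(outdir)
    reuse = (
        prev is not None and db_fa.exists()
        and prev.get("input_digests", {}).get("genome") == manifest.input_digests["genome"]
        and prev.get("config", {}).get("min_orf_aa", 41) == cfg.get("min_orf_aa", 41)
    )
    if reuse:
        logger.info("db stage: reusing cached %s", db_fa)
        db = read_search_db(db_fa)
    else:
        orfs = enumerate_orfs(genomes, min_length_aa=cfg.get("min_orf_aa", 41))
        db = build_search_db(orfs, cfg.get("contaminants"), db_fa,
                             cfg.get("min_orf_aa", 41))
    manifest.outputs["db"] = str(db_fa)
    manifest.stage_seconds["build_db"] = round(time.perf_counter() - t0, 3)

    annotation = read_annotation(path_of("annotation"), genomes)
    manifest.input_digests["annotation"] = _digest(path_of("annotation"))

    # --- stage: map + refine
    t0 = time.perf_counter()
    psms = read_psm_table(path_of("psms"))
    manifest.input_digests["psms"] = _digest(path_of("psms"))
    transcription = None
    if cfg.get("transcription"):
        transcription = _read_flag_table(path_of("transcription"))
    homology = None
    if cfg.get("homology"):
        homology = _read_flag_table(path_of("homology"))
    result = refine_all(genomes, db, annotation, psms, pc,
                        homology_support=homology,
                        transcription_evidence=transcription,
                        tag_prefix=cfg.get("tag_prefix", "PG"))
    manifest.stage_seconds["map_refine"] = round(time.perf_counter() - t0, 3)

    mapped_tsv = outdir / "mapped.tsv"
    _write_mapped(result, mapped_tsv)
    manifest.outputs["mapped"] = str(mapped_tsv)

    fdr = {}
    if cfg.get("decoy_psms"):
        decoys = filter_psms(read_psm_table(path_of("decoy_psms")), pc.psm_p_max)
        targets = filter_psms(psms, pc.psm_p_max)
        fdr = {
            "peptide_fdr_distinct": decoy_fdr(targets, decoys, "peptide"),
            "protein_fdr_distinct": decoy_fdr(targets, decoys, "protein"),
            "peptide_fdr_spectral": decoy_fdr(targets, decoys, "peptide", "spectral"),
        }

    # --- stage: ortho extension
    clade_hits, clade_calls, clade_rate = [], [], None
    if cfg.get("clade_dir"):
        t0 = time.perf_counter()
        clade_hits, clade_calls, clade_rate = _run_ortho(
            Path(path_of("clade_dir")), genomes, result, pc, annotation)
        manifest.stage_seconds["ortho"] = round(time.perf_counter() - t0, 3)

    # --- reports
    report_paths = write_reports(result.calls, clade_hits, outdir,
                                 genomes=genomes, result=result, fdr=fdr,
                                 clade_calls=clade_calls, clade_rate=clade_rate,
                                 annotation=annotation)
    manifest.outputs.update(report_paths)
    manifest.write(outdir / "manifest.json")
    return manifest


def _previous_manifest(outdir: Path) -> dict | None:
    p = outdir / "manifest.json"
    if not p.exists():
        return None
    try:
        return json.loads(p.read_text())
    except json.JSONDecodeError:
        return None


def _write_mapped(result: RefinementResult, path: Path) -> None:
    lines = ["peptide\torf_id\tgenomic_start\tgenomic_end\tframe\tstatus\tshared"]
    for m in sorted(result.mapped, key=lambda m: (m.orf.replicon_id, m.left,
                                                  m.peptide.sequence)):
        lines.append(f"{m.peptide.sequence}\t{m.orf.orf_id}\t{m.genomic_start}"
                     f"\t{m.genomic_end}\t{m.frame:+d}\t{m.peptide.tryptic_status}"
                     f"\t{int(m.shared)}")
    path.write_text("\n".join(lines) + "\n")


def _run_ortho(clade_dir: Path, genomes, result: RefinementResult,
               pc: PipelineConfig, annotation: AnnotationSet | None = None):
    subj_genomes, subj_annotations, subj_proteomes = {}, {}, {}
    for fa in sorted(clade_dir.glob("*.fa")) + sorted(clade_dir.glob("*.fasta")):
        recs = read_genome(fa)
        name = fa.stem
        subj_genomes[name] = recs[0]
        gff = fa.with_suffix(".gff3")
        if gff.exists():
            ann = read_annotation(gff, recs)
            subj_annotations[name] = ann
            subj_proteomes[name] = [
                (c.locus_tag, extract_and_translate(recs[0], c)) for c in ann
            ]
    by_id = {g.replicon_id: g for g in genomes}
    novel = []
    for c in result.calls:
        if c.category in ("novel_cds", "wrong_cds_replacement") and c.new_cds:
            novel.append((c.new_cds.locus_tag,
                          extract_and_translate(by_id[c.new_cds.replicon_id], c.new_cds)))
    hits = find_unannotated_homologs(novel, subj_genomes, subj_annotations, pc)
    nterm = []
    for c in result.calls:
        if c.category in ("start_confirmed", "start_corrected") and c.locus_tag:
            cds = c.new_cds
            if cds is None and annotation is not None:
                try:
                    cds = annotation.by_tag(c.locus_tag)
                except KeyError:
                    cds = None
            if cds is None:
                continue
            nterm.append((c.locus_tag,
                          extract_and_translate(by_id[cds.replicon_id], cds)))
    calls, rate = propagate_start_corrections(nterm, subj_proteomes, subj_genomes,
                                              subj_annotations, pc)
    return hits, calls, rate


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def coverage_percent(call, mapped, genome) -> int:
    """Percent of proposed-CDS residues covered by >=1 mapped peptide,
    rounded half-up to an integer."""
    cds = call.new_cds
    if cds is None:
        return 0
    length = coords_to_length(cds.start_coord, cds.stop_coord)
    prot_len = max(length - 1, 1)  # span includes the stop codon
    covered = set()
    for m in mapped:
        if m.orf.orf_id != call.orf_id:
            continue
        lo, hi = sorted((m.genomic_start, m.genomic_end))
        if hi < cds.left or lo > cds.right:
            continue
        if cds.strand == "+":
            a = (lo - cds.start_coord) // 3
            b = (hi - cds.start_coord) // 3
        else:
            a = (cds.start_coord - hi) // 3
            b = (cds.start_coord - lo) // 3
        covered.update(range(max(a, 0), min(b, prot_len - 1) + 1))
    import math

    return int(math.floor(100 * len(covered) / prot_len + 0.5))


def write_reports(calls, clade_hits, outdir, genomes=None, result=None,
                  fdr=None, clade_calls=None, clade_rate=None,
                  annotation=None) -> dict:
    """Write the call table, clade tables, revised GFF3 and summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    mapped = result.mapped if result is not None else []
    by_id = {g.replicon_id: g for g in genomes} if genomes else {}

    lines = ["target\tcategory\tstart\tstop\tlength_aa\tpeptides\tcoverage"
             "\tdisplaced_locus\tnterm_category\tnote"]
    for c in calls:
        tag = (c.new_cds.locus_tag if c.new_cds is not None
               else (c.locus_tag or c.orf_id or ""))
        if c.new_cds is not None:
            start, stop = c.new_cds.start_coord, c.new_cds.stop_coord
            length = coords_to_length(start, stop) - 1
            genome = by_id.get(c.new_cds.replicon_id)
            cov = f"{coverage_percent(c, mapped, genome)}%" if genome else ""
        elif c.sequence_error is not None:
            lo, hi = c.sequence_error.correction_interval
            start, stop, length = lo, hi, len(c.sequence_error.corrected_protein)
            cov = ""
        else:
            start = stop = length = ""
            cov = ""
        npep = (len(c.evidence.get("peptides", []))
                or len(c.evidence.get("upstream_peptides", []))
                or (1 if "peptide" in c.evidence else 0))
        lines.append(f"{tag}\t{c.category}\t{start}\t{stop}\t{length}\t{npep}"
                     f"\t{cov}\t{c.displaced_locus or ''}\t{c.nterm_category}"
                     f"\t{c.note}")
    calls_tsv = outdir / "calls.tsv"
    calls_tsv.write_text("\n".join(lines) + "\n")
    paths["calls"] = str(calls_tsv)

    lines = ["query\tsubject\treplicon\tstart_5p\tstop_3p\te_value"]
    for h in clade_hits or []:
        lines.append(f"{h.query_id}\t{h.subject_id}\t{h.subject_replicon}"
                     f"\t{h.subject_start}\t{h.subject_stop}\t{h.e_value:.2g}")
    t2 = outdir / "clade_novel.tsv"
    t2.write_text("\n".join(lines) + "\n")
    paths["clade_novel"] = str(t2)

    if clade_calls is not None:
        lines = ["query\tsubject\tsubject_locus\tverdict\tproposed_start"
                 "\toffset_codons\te_value"]
        for c in clade_calls:
            lines.append(f"{c.query_id}\t{c.subject_id}\t{c.subject_locus}"
                         f"\t{c.verdict}\t{c.proposed_start or ''}"
                         f"\t{c.offset_codons}\t{c.e_value:.2g}")
        t3 = outdir / "clade_starts.tsv"
        t3.write_text("\n".join(lines) + "\n")
        paths["clade_starts"] = str(t3)

    # revised annotation
    if annotation is not None:
        revised = _apply_calls(annotation, calls)
        gff = outdir / "revised.gff3"
        write_annotation(revised, gff)
        paths["revised_gff3"] = str(gff)

    # summary
    from collections import Counter

    counts = Counter(c.category for c in calls)
    usage = start_codon_usage(calls)
    s = ["proteoseed summary", "=" * 18]
    for cat in sorted(counts):
        s.append(f"{cat}: {counts[cat]}")
    if usage:
        s.append("start codon usage: " + ", ".join(
            f"{c} {usage.get(c, 0):.0f}%" for c in ("ATG", "GTG", "TTG")))
    for k, v in (fdr or {}).items():
        s.append(f"{k}: {100 * v:.2f}%")
    if clade_rate is not None:
        s.append(f"clade start-correction rate: {100 * clade_rate:.1f}%")
    summary = outdir / "summary.txt"
    summary.write_text("\n".join(s) + "\n")
    paths["summary"] = str(summary)
    return paths


def _apply_calls(annotation: AnnotationSet, calls) -> AnnotationSet:
    """Published annotation with displaced loci removed and calls applied."""
    out = {c.locus_tag: c for c in annotation}
    for c in calls:
        if c.category == "wrong_cds_replacement":
            for tag in c.evidence.get("displaced_loci", [c.displaced_locus]):
                out.pop(tag, None)
    for c in calls:
        if c.new_cds is None:
            continue
        if c.category in ("novel_cds", "wrong_cds_replacement", "nterm_extension",
                          "start_corrected"):
            out[c.new_cds.locus_tag] = c.new_cds
    return AnnotationSet(sorted(out.values(), key=lambda c: (c.replicon_id, c.left)))
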