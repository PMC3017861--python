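"""Pipeline orchestration, ground-truth evaluation, and report tables.

``run_pipeline`` drives the full analysis — simulate (or load) a library,
clean, assemble, annotate, and mine variants/repeats — persisting every
intermediate as a plain text file so any stage can be re-run or inspected
in isolation.  ``evaluate_against_truth`` scores the calls against the
generator's registry, and ``write_reports`` emits the summary tables
(abundance with both denominators, SNPs per contig with the first hit,
TE families, chimeras, inverted repeats, microsatellites).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import yaml

from .align import ScoringScheme, smith_waterman
from .annotate import (
    Annotation,
    ClassAbundance,
    ReferenceRecord,
    annotate_unisequences,
    load_references,
    summarize_abundance,
)
from .assembly import AssemblyParams, build_unisequences
from .cleaning import CleaningParams, CleaningReport, clean_pipeline
from .io_utils import write_fasta, write_fasta_qual
from .repeats import (
    ChimeraCall,
    InvertedRepeat,
    IrParams,
    RepeatSearchParams,
    TEAnnotation,
    classify_chimera,
    detect_inverted_repeats,
    detect_tes,
    summarize_te_families,
)
from .simulate import (
    GeneratorConfig,
    GroundTruth,
    SyntheticWorld,
    build_world,
    generate_library,
)
from .variants import (
    IndelCall,
    MicrosatThresholds,
    SNPCall,
    SnpParams,
    TandemRepeat,
    call_indels,
    call_snps,
    classify_contig_snps,
    exclude_te_overlaps,
    mine_microsatellites,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "EvaluationReport",
    "run_pipeline",
    "evaluate_against_truth",
    "write_reports",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Every stage's parameter block plus the global seed."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cleaning: CleaningParams = field(default_factory=CleaningParams)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    snp: SnpParams = field(default_factory=SnpParams)
    repeat: RepeatSearchParams = field(default_factory=RepeatSearchParams)
    ir: IrParams = field(default_factory=IrParams)
    microsat: MicrosatThresholds = field(default_factory=MicrosatThresholds)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    evalue_cutoff: float = 1e-5
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed,
                       generator=replace(self.generator, seed=seed))

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "evalue_cutoff": self.evalue_cutoff,
            "generator": asdict(self.generator),
            "cleaning": asdict(self.cleaning),
            "assembly": asdict(self.assembly),
            "snp": asdict(self.snp),
            "repeat": asdict(self.repeat),
            "ir": asdict(self.ir),
            "microsat": asdict(self.microsat),
            "scoring": asdict(self.scoring),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        from .simulate import DecorationModel, LengthModel

        kwargs = {}
        gen = dict(payload.get("generator", {}))
        if gen:
            if "length_model" in gen:
                gen["length_model"] = LengthModel(**gen["length_model"])
            if "decoration_model" in gen:
                dm = dict(gen["decoration_model"])
                for key in ("vector_len_range", "polya_len_range"):
                    if key in dm:
                        dm[key] = tuple(dm[key])
                gen["decoration_model"] = DecorationModel(**dm)
            kwargs["generator"] = GeneratorConfig(**gen)
        for name, klass in (("cleaning", CleaningParams), ("assembly", AssemblyParams),
                            ("snp", SnpParams), ("repeat", RepeatSearchParams),
                            ("ir", IrParams), ("microsat", MicrosatThresholds)):
            if name in payload:
                kwargs[name] = klass(**payload[name])
        if "scoring" in payload:
            sc = dict(payload["scoring"])
            if "background" in sc:
                sc["background"] = tuple(sc["background"])
            kwargs["scoring"] = ScoringScheme(**sc)
        for name in ("seed", "evalue_cutoff"):
            if name in payload:
                kwargs[name] = payload[name]
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Result bundle
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    config: PipelineConfig
    reads: list
    truth: GroundTruth | None
    world: SyntheticWorld | None
    cleaned: list
    cleaning_report: CleaningReport
    unisequences: list
    annotations: dict  # unisequence id -> Annotation
    abundance: ClassAbundance
    snps: list
    indels: list
    microsatellites: list
    microsatellites_te_excluded: list
    te_annotations: list
    te_family_table: list
    chimeras: list
    inverted_repeats: list

    @property
    def contigs(self):
        return [u for u in self.unisequences if u.kind == "contig"]

    @property
    def singletons(self):
        return [u for u in self.unisequences if u.kind == "singleton"]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    *,
    reads: list | None = None,
    world: SyntheticWorld | None = None,
    truth: GroundTruth | None = None,
    log=lambda msg: None,
) -> PipelineResult:
    """Simulate -> clean -> assemble -> annotate -> mine, with artifacts.

    When ``reads`` is not supplied, a synthetic library is generated from
    ``config.generator``.  Identical config + seed give identical results.
    """
    config = config or PipelineConfig()
    scheme = config.scoring if config.scoring.is_calibrated else config.scoring.calibrated()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    if world is None:
        world = build_world(config.generator, config.seed)
    if reads is None:
        log(f"simulating {config.generator.n_reads} reads (seed {config.seed})")
        reads, truth = generate_library(config.generator, world, config.seed)
    references = load_references(world.reference_records())
    repeat_library = list(world.repeat_library)
    families = dict(world.repeat_families)
    vectors = list(world.vectors)

    if out is not None:
        write_fasta_qual(reads, out / "reads.fasta", out / "reads.qual")
        write_fasta([(r.id, r.sequence) for r in references], out / "references.fasta",
                    {r.id: _ref_description(r) for r in references})
        write_fasta(repeat_library, out / "repeats.fasta",
                    {rid: f"family={families[rid]}" for rid, _ in repeat_library})
        write_fasta(vectors, out / "vectors.fasta")
        if truth is not None:
            truth.to_json(out / "ground_truth.json")

    log("cleaning reads")
    cleaned, cleaning_report = clean_pipeline(reads, vectors, scheme, config.cleaning)
    if out is not None:
        write_fasta_qual(cleaned, out / "cleaned.fasta", out / "cleaned.qual")
        (out / "cleaning_report.tsv").write_text(cleaning_report.to_tsv())

    log(f"assembling {len(cleaned)} cleaned reads")
    unisequences = build_unisequences(cleaned, scheme, config.assembly)
    if out is not None:
        write_fasta([(u.id, u.sequence) for u in unisequences],
                    out / "unisequences.fasta")
        (out / "membership.tsv").write_text(_membership_tsv(unisequences))

    log(f"annotating {len(unisequences)} unisequences")
    ann_list = annotate_unisequences(unisequences, references, scheme,
                                     config.evalue_cutoff)
    annotations = {a.unisequence_id: a for a in ann_list}
    abundance = summarize_abundance(ann_list)

    log("mining SNPs and indels")
    snps, indels = [], []
    for u in unisequences:
        if u.contig is None:
            continue
        contig_snps = call_snps(u.contig, config.snp)
        classify_contig_snps(contig_snps, annotations.get(u.id), u.sequence)
        snps.extend(contig_snps)
        indels.extend(call_indels(u.contig, config.snp))

    log("mining microsatellites, TEs, chimeras and inverted repeats")
    microsats = mine_microsatellites(unisequences, config.microsat)
    te_annotations, chimeras, irs = [], [], []
    for u in unisequences:
        tes = detect_tes(u.sequence, repeat_library, scheme, config.repeat,
                         families=families, unisequence_id=u.id)
        te_annotations.extend(tes)
        if tes:
            call, reason = classify_chimera(u.sequence, tes, references, scheme,
                                            config.repeat, unisequence_id=u.id)
            if call is not None:
                chimeras.append(call)
        irs.extend(detect_inverted_repeats(u.sequence, scheme, config.ir,
                                           unisequence_id=u.id))
    microsats_excl = exclude_te_overlaps(microsats, te_annotations)
    family_table = summarize_te_families(te_annotations)

    result = PipelineResult(
        config=config, reads=reads, truth=truth, world=world, cleaned=cleaned,
        cleaning_report=cleaning_report, unisequences=unisequences,
        annotations=annotations, abundance=abundance, snps=snps, indels=indels,
        microsatellites=microsats, microsatellites_te_excluded=microsats_excl,
        te_annotations=te_annotations, te_family_table=family_table,
        chimeras=chimeras, inverted_repeats=irs,
    )
    if out is not None:
        write_reports(result, out)
    return result


def run_composition(config: PipelineConfig | None = None) -> dict:
    """Clean -> assemble -> annotate on a synthetic library and return the
    headline composition numbers (mining stages are skipped).

    Percentages are EST-level, on the scale a library report prints them
    (0-100).  Used by the reproduction script and the composition tests.
    """
    config = config or PipelineConfig()
    scheme = (config.scoring if config.scoring.is_calibrated
              else config.scoring.calibrated())
    world = build_world(config.generator, config.seed)
    reads, truth = generate_library(config.generator, world, config.seed)
    references = load_references(world.reference_records())
    cleaned, report = clean_pipeline(reads, world.vectors, scheme, config.cleaning)
    unisequences = build_unisequences(cleaned, scheme, config.assembly)
    anns = annotate_unisequences(unisequences, references, scheme,
                                 config.evalue_cutoff, with_frames=False)
    ab = summarize_abundance(anns)
    per_toxin = ab.class_pct_of_toxin
    return {
        "n_reads": len(reads),
        "n_cleaned": len(cleaned),
        "metalloproteinase_pct_of_toxin": per_toxin.get("metalloproteinase", 0.0),
        "bpp_cnp_pct_of_toxin": per_toxin.get("BPP/CNP", 0.0),
        "toxin_pct_of_total": ab.toxin_pct_of_total,
        "toxin_pct_of_hits": ab.toxin_pct_of_hits,
        "hit_pct_of_total": ab.hit_pct_of_total,
        "mean_cleaned_length": (float(np.mean([len(r) for r in cleaned]))
                                if cleaned else 0.0),
    }


def _ref_description(r: ReferenceRecord) -> str:
    desc = f"class={r.class_label}"
    if r.cds_start is not None:
        desc += f" cds_start={r.cds_start} cds_end={r.cds_end}"
    return desc


def _membership_tsv(unisequences) -> str:
    lines = ["unisequence\tkind\tmember_count\tmembers"]
    for u in unisequences:
        lines.append(f"{u.id}\t{u.kind}\t{u.member_count}\t"
                     + ",".join(u.member_read_ids))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Evaluation against ground truth
# ---------------------------------------------------------------------------


@dataclass
class EvaluationReport:
    per_feature: dict  # type -> {n_planted, n_called, matched, sensitivity, precision}
    abundance: dict  # recovered vs configured percentages
    assembly: dict  # contig/singleton counts, reads per unisequence, identity

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"per_feature": self.per_feature, "abundance": self.abundance,
             "assembly": self.assembly}, indent=1, sort_keys=True))


class _UniMap:
    """Coordinate map from one unisequence to its majority template."""

    def __init__(self, template_id, orientation, offset, n_members):
        self.template_id = template_id
        self.orientation = orientation  # layout/forward-seq vs template
        self.offset = offset
        self.n_members = n_members

    def to_template(self, pos: int) -> int:
        if self.orientation == "forward":
            return self.offset + pos
        return self.offset - pos

    def interval(self, a: int, b: int) -> tuple[int, int]:
        x, y = self.to_template(a), self.to_template(b - 1)
        lo, hi = (x, y) if x <= y else (y, x)
        return lo, hi + 1


def _build_unimaps(result: PipelineResult, truth: GroundTruth) -> dict:
    maps = {}
    for u in result.unisequences:
        truths = [truth.reads[r] for r in u.member_read_ids if r in truth.reads]
        if not truths:
            continue
        tpl = Counter(t.template_id for t in truths).most_common(1)[0][0]
        if u.contig is None:
            rt = truths[0]
            if rt.strand == "forward":
                maps[u.id] = _UniMap(tpl, "forward", rt.tpl_start, 1)
            else:
                maps[u.id] = _UniMap(tpl, "reverse", rt.tpl_end - 1, 1)
            continue
        fwd_off, rev_off = [], []
        for m in u.contig.members:
            rt = truth.reads.get(m.read_id)
            if rt is None or rt.template_id != tpl:
                continue
            if (rt.strand == "forward") == (m.strand == "forward"):
                fwd_off.append(rt.tpl_start - m.offset)
            else:
                rev_off.append(rt.tpl_end - 1 + m.offset)
        # layout-column coordinates; consensus positions are mapped to
        # columns by the caller before using this map
        if len(fwd_off) >= len(rev_off):
            maps[u.id] = _UniMap(tpl, "forward", int(np.median(fwd_off)), len(fwd_off))
        else:
            maps[u.id] = _UniMap(tpl, "reverse", int(np.median(rev_off)), len(rev_off))
    return maps


def _snp_template_positions(snp: SNPCall, contig, truth: GroundTruth,
                            features_by_tpl: dict) -> list[int]:
    """Exact template coordinates of a SNP column, voted across reads."""
    votes = []
    col = snp.column
    for m in contig.members:
        at = col - m.offset
        if not (0 <= at < len(m.aligned)) or m.aligned[at] == "-":
            continue
        rt = truth.reads.get(m.read_id)
        if rt is None:
            continue
        read_idx = sum(1 for c in m.aligned[:at] if c != "-")
        read_len = sum(1 for c in m.aligned if c != "-")
        if m.strand == "reverse":
            read_idx = read_len - 1 - read_idx
        core_idx = read_idx if rt.strand == "forward" else None
        if rt.strand == "reverse":
            core_idx = read_len - 1 - read_idx
        # undo per-read deletion alleles planted before this position
        shift = 0
        for rec in features_by_tpl.get(rt.template_id, []):
            if rec["type"] != "indel":
                continue
            if rt.alleles.get(rec["locus_id"]) == 1:
                p0 = rec["position"] - rt.tpl_start
                if 0 <= p0 <= core_idx:
                    shift += rec["length"]
        votes.append(rt.tpl_start + core_idx + shift)
    return votes


def evaluate_against_truth(
    result: PipelineResult,
    truth: GroundTruth | None = None,
    interval_tolerance: int = 5,
    snp_tolerance: int = 0,
) -> EvaluationReport:
    """Sensitivity/precision per feature type against the planted registry.

    A call matches a planted feature iff its unisequence maps to the
    feature's template, the type agrees, and coordinates agree within the
    tolerance (0 for SNPs, +-``interval_tolerance`` for interval
    features).  Precision for an empty call set is reported as None.
    """
    truth = truth if truth is not None else result.truth
    if truth is None:
        raise ValueError("no ground truth available for evaluation")
    maps = _build_unimaps(result, truth)
    features_by_tpl: dict[str, list] = {}
    for rec in truth.features:
        features_by_tpl.setdefault(rec["template"], []).append(rec)

    per_feature = {}

    def score(feature_type, planted, called, match_fn):
        # many-to-one: a planted feature may be recovered on several
        # unisequences (a template can tile into more than one contig)
        matched_planted = set()
        matched_calls = 0
        for call in called:
            ok = False
            for pi, rec in enumerate(planted):
                if match_fn(call, rec):
                    matched_planted.add(pi)
                    ok = True
            if ok:
                matched_calls += 1
        n_p, n_c = len(planted), len(called)
        per_feature[feature_type] = {
            "n_planted": n_p, "n_called": n_c, "matched": len(matched_planted),
            "sensitivity": (len(matched_planted) / n_p) if n_p else None,
            "precision": (matched_calls / n_c) if n_c else None,
        }

    contigs_by_id = {u.id: u.contig for u in result.unisequences if u.contig}

    # ---- SNPs (exact position through read-level voting) ----------------
    planted_snps = [r for r in truth.features if r["type"] == "snp"]

    def snp_match(call: SNPCall, rec) -> bool:
        m = maps.get(call.contig_id)
        if m is None or m.template_id != rec["template"]:
            return False
        votes = _snp_template_positions(call, contigs_by_id[call.contig_id],
                                        truth, features_by_tpl)
        if not votes:
            return False
        pos = Counter(votes).most_common(1)[0][0]
        return abs(pos - rec["position"]) <= snp_tolerance

    score("snp", planted_snps, result.snps, snp_match)

    # ---- indels ---------------------------------------------------------
    planted_indels = [r for r in truth.features if r["type"] == "indel"]

    def indel_match(call: IndelCall, rec) -> bool:
        m = maps.get(call.contig_id)
        if m is None or m.template_id != rec["template"]:
            return False
        lo, hi = m.interval(call.col_start, call.col_end)
        return abs(lo - rec["position"]) <= interval_tolerance

    score("indel", planted_indels, result.indels, indel_match)

    # ---- microsatellites (planted only; others are chance arrays) -------
    planted_ssrs = [r for r in truth.features if r["type"] == "microsatellite"]

    def ssr_match(call: TandemRepeat, rec) -> bool:
        m = maps.get(call.unisequence_id)
        if m is None or m.template_id != rec["template"]:
            return False
        lo, hi = m.interval(call.start, call.end)
        return (abs(lo - rec["start"]) <= interval_tolerance
                and abs(hi - rec["end"]) <= interval_tolerance)

    # microsatellite precision is measured against *planted* arrays only
    # on templates that carry them; chance arrays elsewhere are excluded
    ssr_calls = [c for c in result.microsatellites
                 if maps.get(c.unisequence_id)
                 and any(r["type"] == "microsatellite"
                         for r in features_by_tpl.get(
                             maps[c.unisequence_id].template_id, []))]
    score("microsatellite", planted_ssrs, ssr_calls, ssr_match)

    # ---- TEs ------------------------------------------------------------
    planted_tes = [r for r in truth.features if r["type"] == "te"]

    def te_match(call: TEAnnotation, rec) -> bool:
        m = maps.get(call.unisequence_id)
        if m is None or m.template_id != rec["template"]:
            return False
        if call.repeat_id != rec["repeat_id"]:
            return False
        lo, hi = m.interval(call.q_start, call.q_end)
        # the unisequence may cover only part of the planted element
        return not (hi <= rec["start"] or lo >= rec["end"])

    score("te", planted_tes, result.te_annotations, te_match)

    # ---- chimeras (template-level identity) -----------------------------
    planted_chims = [r for r in truth.features if r["type"] == "chimera"]

    def chim_match(call: ChimeraCall, rec) -> bool:
        m = maps.get(call.unisequence_id)
        return m is not None and m.template_id == rec["template"]

    score("chimera", planted_chims, result.chimeras, chim_match)

    # ---- inverted repeats ----------------------------------------------
    planted_irs = [r for r in truth.features if r["type"] == "inverted_repeat"]

    def ir_match(call: InvertedRepeat, rec) -> bool:
        # overlap-based: a unisequence may cover the planted IR partially
        m = maps.get(call.unisequence_id)
        if m is None or m.template_id != rec["template"]:
            return False
        a = m.interval(call.left_start, call.left_end)
        b = m.interval(call.right_start, call.right_end)
        (a, b) = (a, b) if a[0] <= b[0] else (b, a)
        return (a[0] < rec["left_end"] and rec["left_start"] < a[1]
                and b[0] < rec["right_end"] and rec["right_start"] < b[1])

    score("inverted_repeat", planted_irs, result.inverted_repeats, ir_match)

    # ---- abundance recovery --------------------------------------------
    ab = result.abundance
    expected = truth.expected
    abundance = {
        "hit_pct_of_total": {"recovered": ab.hit_pct_of_total,
                             "configured": 100 * expected["hit_fraction_of_total"]},
        "toxin_pct_of_total": {"recovered": ab.toxin_pct_of_total,
                               "configured": 100 * expected["toxin_fraction_of_total"]},
        "toxin_pct_of_hits": {
            "recovered": ab.toxin_pct_of_hits,
            "configured": (100 * expected["toxin_fraction_of_total"]
                           / expected["hit_fraction_of_total"]),
        },
        "class_pct_of_toxin": {
            cls: {"recovered": ab.class_pct_of_toxin.get(cls, 0.0),
                  "configured": 100 * frac}
            for cls, frac in expected["toxin_class_mixture"].items()
        },
    }

    # ---- assembly metrics ----------------------------------------------
    contigs = result.contigs
    assembly = {
        "n_contigs": len(contigs),
        "n_singletons": len(result.singletons),
        "mean_reads_per_unisequence": (
            float(np.mean([u.member_count for u in result.unisequences]))
            if result.unisequences else 0.0),
    }
    if result.world is not None and contigs:
        idents = []
        scheme = (result.config.scoring if result.config.scoring.is_calibrated
                  else result.config.scoring.calibrated())
        for u in contigs:
            m = maps.get(u.id)
            if m is None:
                continue
            tpl = result.world.templates.get(m.template_id)
            if tpl is None:
                continue
            hits = smith_waterman(u.sequence, tpl.sequence, scheme, 30, max_hits=1)
            if not hits:
                hits = smith_waterman(u.sequence[::-1].translate(
                    str.maketrans("ACGT", "TGCA")), tpl.sequence, scheme, 30,
                    max_hits=1)
            if hits:
                idents.append(hits[0].identity)
        if idents:
            assembly["mean_consensus_identity"] = float(np.mean(idents))

    return EvaluationReport(per_feature=per_feature, abundance=abundance,
                            assembly=assembly)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def _fmt_pct(x: float) -> str:
    return f"{x:.1f}"


def write_reports(result: PipelineResult, outdir: str | Path) -> None:
    """Emit the paper-style report tables (1-based inclusive coordinates,
    percentages to one decimal)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ab = result.abundance

    # abundance with both denominators
    lines = ["class\tests\tpct_of_total\tpct_of_toxin"]
    per_tox = ab.class_pct_of_toxin
    for cls in sorted(ab.per_class_ests, key=lambda c: -ab.per_class_ests[c]):
        n = ab.per_class_ests[cls]
        lines.append(f"{cls}\t{n}\t{_fmt_pct(100 * n / ab.total_ests)}\t"
                     + (_fmt_pct(per_tox[cls]) if cls in per_tox else ""))
    lines.append(f"no_hit\t{ab.no_hit_ests}\t"
                 f"{_fmt_pct(100 * ab.no_hit_ests / ab.total_ests)}\t")
    (out / "abundance.tsv").write_text("\n".join(lines) + "\n")
    (out / "abundance.json").write_text(json.dumps({
        "total_ests": ab.total_ests,
        "hit_ests": ab.hit_ests,
        "toxin_ests": ab.toxin_ests,
        "hit_pct_of_total": round(ab.hit_pct_of_total, 1),
        "toxin_pct_of_total": round(ab.toxin_pct_of_total, 1),
        "toxin_pct_of_hits": round(ab.toxin_pct_of_hits, 1),
        "class_pct_of_toxin": {k: round(v, 1) for k, v in per_tox.items()},
        "class_pct_of_total": {k: round(v, 1)
                               for k, v in ab.class_pct_of_total.items()},
    }, indent=1, sort_keys=True))

    # SNP-per-contig table with the first-hit column
    snp_by_contig: dict[str, list] = {}
    for s in result.snps:
        snp_by_contig.setdefault(s.contig_id, []).append(s)
    lines = ["contig\tlength_bp\tsnps\tsyn\tnonsyn\tfirst_hit"]
    uni_by_id = {u.id: u for u in result.unisequences}
    for cid in sorted(snp_by_contig, key=lambda c: -len(snp_by_contig[c])):
        snps = snp_by_contig[cid]
        ann = result.annotations.get(cid)
        first_hit = ann.best_hit.subject_id if ann and ann.best_hit else "no_hit"
        syn = sum(1 for s in snps if s.classification == "synonymous")
        nsyn = sum(1 for s in snps if s.classification == "nonsynonymous")
        lines.append(f"{cid}\t{len(uni_by_id[cid].sequence)}\t{len(snps)}\t"
                     f"{syn}\t{nsyn}\t{first_hit}")
    (out / "snp_table.tsv").write_text("\n".join(lines) + "\n")

    lines = ["contig\tcolumns\tbases\twith_support\twithout_support\tplates"]
    for c in result.indels:
        lines.append(f"{c.contig_id}\t{c.col_start + 1}-{c.col_end}\t{c.bases}\t"
                     f"{c.with_support}\t{c.without_support}\t"
                     + ",".join(map(str, c.plates)))
    (out / "indel_table.tsv").write_text("\n".join(lines) + "\n")

    # TE family table
    lines = ["family\tname\tunisequences"]
    for fam, name, count in result.te_family_table:
        lines.append(f"{fam}\t{name}\t{count}")
    (out / "te_families.tsv").write_text("\n".join(lines) + "\n")

    lines = ["unisequence\trepeat\tfamily\tstart\tend\tidentity\tevalue\tcoverage"]
    for t in result.te_annotations:
        lines.append(f"{t.unisequence_id}\t{t.repeat_id}\t{t.family}\t"
                     f"{t.q_start + 1}\t{t.q_end}\t{100 * t.identity:.1f}\t"
                     f"{t.evalue:.2e}\t{100 * t.coverage:.1f}")
    (out / "te_annotations.tsv").write_text("\n".join(lines) + "\n")

    lines = ["unisequence\thost\thost_fraction\thost_identity\tmasked_intervals"]
    for c in result.chimeras:
        ivs = ";".join(f"{a + 1}-{b}" for a, b in c.masked_intervals)
        lines.append(f"{c.unisequence_id}\t{c.host_hit.subject_id}\t"
                     f"{100 * c.host_fraction:.1f}\t{100 * c.host_identity:.1f}\t{ivs}")
    (out / "chimeras.tsv").write_text("\n".join(lines) + "\n")

    lines = ["unisequence\tleft_arm\tright_arm\tarm_length\tinter_ir_length"
             "\tmismatches\tmismatch_pct"]
    for i in result.inverted_repeats:
        lines.append(
            f"{i.unisequence_id}\t{i.left_start + 1}-{i.left_end}\t"
            f"{i.right_start + 1}-{i.right_end}\t{i.arm_length}\t"
            f"{i.inter_ir_length}\t{i.mismatches}\t"
            f"{100 * i.mismatch_fraction:.1f}")
    (out / "inverted_repeats.tsv").write_text("\n".join(lines) + "\n")

    lines = ["unisequence\tmotif\tcopies\tstart\tend\tte_excluded"]
    excluded_ids = {r.unisequence_id for r in result.microsatellites} - {
        r.unisequence_id for r in result.microsatellites_te_excluded}
    for r in result.microsatellites:
        lines.append(f"{r.unisequence_id}\t{r.motif}\t{r.copies:.1f}\t"
                     f"{r.start + 1}\t{r.end}\t"
                     f"{'yes' if r.unisequence_id in excluded_ids else 'no'}")
    (out / "microsatellites.tsv").write_text("\n".join(lines) + "\n")

    summary = {
        "reads": len(result.reads),
        "cleaned_reads": len(result.cleaned),
        "cleaning": result.cleaning_report.counts,
        "contigs": len(result.contigs),
        "singletons": len(result.singletons),
        "hit_pct_of_total": round(ab.hit_pct_of_total, 1),
        "toxin_pct_of_total": round(ab.toxin_pct_of_total, 1),
        "toxin_pct_of_hits": round(ab.toxin_pct_of_hits, 1),
        "class_pct_of_toxin": {k: round(v, 1) for k, v in per_tox.items()},
        "mean_cleaned_length": (round(float(np.mean([len(r) for r in result.cleaned])), 1)
                                if result.cleaned else 0.0),
        "snps": len(result.snps),
        "indels": len(result.indels),
        "microsatellite_unisequences": len({r.unisequence_id
                                            for r in result.microsatellites}),
        "microsatellite_unisequences_te_excluded": len({
            r.unisequence_id for r in result.microsatellites_te_excluded}),
        "te_unisequences": len({t.unisequence_id for t in result.te_annotations}),
        "chimeras": len(result.chimeras),
        "inverted_repeat_unisequences": len({i.unisequence_id
                                             for i in result.inverted_repeats}),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
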