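"""Synthetic venom-gland EST library generator with full ground truth.

Emulates the statistical structure of a snake venom-gland EST project:
a toxin-dominated class mixture (snake venom metalloproteinases ~81% of
toxin transcripts, BPP/CNP precursors ~8.8%, PLA2 ~5.6%, serine
proteinases ~1.9%, C-type lectins ~1.5%), ~30% of transcripts annotatable
against references of which ~78% are toxin-related, single-pass 5' reads
whose post-cleaning lengths follow a truncated normal on [100, 848] bp
with mean 562 bp, three sequencing plates, 5' vector contamination, 3'
polyA tails, a linear 3' PHRED decay, and planted SNPs, indels,
microsatellites, transposable-element insertions, TE-host chimeras and
long inverted repeats.  Every planted feature and every read's provenance
is recorded in a :class:`GroundTruth` registry so downstream callers can
be scored without re-reading any sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .align import reverse_complement
from .io_utils import Read

__all__ = [
    "TOXIN_CLASSES",
    "DEFAULT_TOXIN_MIXTURE",
    "LengthModel",
    "DecorationModel",
    "GeneratorConfig",
    "TemplateSpec",
    "SyntheticWorld",
    "GroundTruth",
    "ReadTruth",
    "PlantingError",
    "build_world",
    "make_reference_collections",
    "generate_library",
    "plant_inverted_repeat",
    "plant_microsatellite",
    "plant_te_insertion",
]

TOXIN_CLASSES = (
    "metalloproteinase",
    "BPP/CNP",
    "PLA2",
    "serine_proteinase",
    "C_type_lectin",
    "other_toxin",
)

#: Toxin-class mixture (fractions of toxin ESTs).  The five named classes
#: follow the published venom-gland profile; the remainder is pooled as
#: "other_toxin" (LAO, CRISPs, DPP IV, ohanin, three-finger toxins, ...).
DEFAULT_TOXIN_MIXTURE = {
    "metalloproteinase": 0.81,
    "BPP/CNP": 0.088,
    "PLA2": 0.056,
    "serine_proteinase": 0.019,
    "C_type_lectin": 0.015,
    "other_toxin": 0.012,
}

_CLASS_CODES = {
    "metalloproteinase": "MET",
    "BPP/CNP": "BPP",
    "PLA2": "PLA",
    "serine_proteinase": "SER",
    "C_type_lectin": "LEC",
    "other_toxin": "OTX",
    "non_toxin": "HST",
    "unknown": "UNK",
}


class PlantingError(ValueError):
    """Raised when a feature cannot be planted into its template."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LengthModel:
    """Truncated-normal model of post-cleaning read length.

    ``mean`` is the target mean of the *truncated* distribution; the
    underlying normal's location is solved numerically so the truncated
    mean hits the target.
    """

    mean: float = 562.0
    sd: float = 150.0
    min_length: int = 100
    max_length: int = 848

    def solved_loc(self) -> float:
        lo, hi, sd = self.min_length, self.max_length, self.sd

        def trunc_mean(loc: float) -> float:
            a, b = (lo - loc) / sd, (hi - loc) / sd
            return float(truncnorm.mean(a, b, loc=loc, scale=sd))

        return float(brentq(lambda L: trunc_mean(L) - self.mean, lo - 2 * sd, hi + 2 * sd))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        loc = self.solved_loc()
        a = (self.min_length - loc) / self.sd
        b = (self.max_length - loc) / self.sd
        u = rng.random(n)
        vals = truncnorm.ppf(u, a, b, loc=loc, scale=self.sd)
        return np.clip(np.rint(vals), self.min_length, self.max_length).astype(int)


@dataclass(frozen=True)
class DecorationModel:
    """Read decorations: 5' vector prefix, 3' polyA tail, PHRED decay."""

    vector_prob: float = 0.3
    vector_len_range: tuple[int, int] = (20, 60)
    polya_prob: float = 0.5
    polya_len_range: tuple[int, int] = (15, 30)
    quality_start: float = 40.0
    quality_slope: float = 0.015  # PHRED units lost per base toward 3'
    quality_jitter_sd: float = 2.0
    quality_floor: int = 2


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for a synthetic EST library."""

    n_reads: int = 5000
    n_plates: int = 3
    toxin_fraction_of_total: float = 0.23
    hit_fraction_of_total: float = 0.30
    toxin_class_mixture: dict = field(default_factory=lambda: dict(DEFAULT_TOXIN_MIXTURE))
    length_model: LengthModel = LengthModel()
    decoration_model: DecorationModel = DecorationModel()
    per_base_error: float = 0.005
    template_counts: dict = field(
        default_factory=lambda: {
            "metalloproteinase": 8,
            "BPP/CNP": 4,
            "PLA2": 3,
            "serine_proteinase": 2,
            "C_type_lectin": 2,
            "other_toxin": 5,
            "non_toxin": 10,
            "unknown": 25,
        }
    )
    n_chimera_templates: int = 3
    n_pure_te_templates: int = 3
    plant_default_features: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0.0 <= self.toxin_fraction_of_total <= self.hit_fraction_of_total <= 1.0:
            raise ValueError("need 0 <= toxin fraction <= hit fraction <= 1")
        total = sum(self.toxin_class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"toxin class mixture sums to {total}, not 1")


# ---------------------------------------------------------------------------
# Templates and world
# ---------------------------------------------------------------------------


@dataclass
class TemplateSpec:
    """One transcript species the library samples reads from."""

    template_id: str
    class_label: str
    sequence: str
    cds_start: int | None
    cds_end: int | None
    abundance_weight: float
    planted_features: list = field(default_factory=list)
    in_reference: bool = True
    sampled: bool = True  # reference-only records are never read from
    host_id: str | None = None  # for TE-host chimera templates


@dataclass
class SyntheticWorld:
    """Templates plus matched reference / repeat / vector collections."""

    templates: dict
    repeat_library: list  # (repeat_id, sequence)
    repeat_families: dict  # repeat_id -> family name
    vectors: list  # (vector_id, sequence)
    features: list  # planted-feature truth dicts (template coordinates)
    snp_loci: list = field(default_factory=list)
    indel_loci: list = field(default_factory=list)

    def group_members(self, group: str) -> list:
        """Templates sampled for a class group, with weights."""
        out = [
            (t.template_id, t.abundance_weight)
            for t in self.templates.values()
            if t.class_label == group and t.sampled
        ]
        out.sort()
        return out

    def reference_records(self) -> list:
        """(id, sequence, description) for every annotatable template.

        Unknown-class templates and chimeric fusion templates are excluded:
        the former must produce no-hits, the latter stand in for novel
        fusions absent from public databases (their host genes are present).
        """
        recs = []
        for tid in sorted(self.templates):
            t = self.templates[tid]
            if t.class_label == "unknown" or not t.in_reference:
                continue
            desc = f"class={t.class_label.replace(' ', '_')}"
            if t.cds_start is not None:
                desc += f" cds_start={t.cds_start} cds_end={t.cds_end}"
            recs.append((tid, t.sequence, desc))
        return recs


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


# ---------------------------------------------------------------------------
# Feature planting primitives
# ---------------------------------------------------------------------------


def plant_inverted_repeat(
    sequence: str,
    position: int,
    arm_length: int,
    inter_ir_length: int,
    arm_mismatch_rate: float,
    rng: np.random.Generator,
) -> tuple[str, dict]:
    """Insert an IR block (arm A + spacer + mutated revcomp of A).

    Returns the modified sequence and a truth record with 0-based
    half-open arm coordinates and the realized mismatch count between the
    right arm and the reverse complement of the left arm.
    """
    if len(sequence) < 2 * arm_length + inter_ir_length:
        raise PlantingError("template too short to host the inverted repeat")
    if not 0 <= position <= len(sequence):
        raise PlantingError("insertion position outside template")
    arm_a = _random_seq(rng, arm_length)
    spacer = _random_seq(rng, inter_ir_length)
    arm_b = list(reverse_complement(arm_a))
    n_mut = 0
    for i in range(arm_length):
        if rng.random() < arm_mismatch_rate:
            choices = [c for c in "ACGT" if c != arm_b[i]]
            arm_b[i] = choices[rng.integers(0, 3)]
            n_mut += 1
    arm_b = "".join(arm_b)
    block = arm_a + spacer + arm_b
    new_seq = sequence[:position] + block + sequence[position:]
    realized = sum(1 for x, y in zip(arm_b, reverse_complement(arm_a)) if x != y)
    assert realized == n_mut
    truth = {
        "type": "inverted_repeat",
        "left_start": position,
        "left_end": position + arm_length,
        "right_start": position + arm_length + inter_ir_length,
        "right_end": position + 2 * arm_length + inter_ir_length,
        "arm_length": arm_length,
        "inter_ir_length": inter_ir_length,
        "mismatches": realized,
    }
    return new_seq, truth


def plant_microsatellite(
    sequence: str, position: int, motif: str, copies: int
) -> tuple[str, dict]:
    """Insert an exact tandem array ``motif * copies`` at ``position``."""
    if not 0 <= position <= len(sequence):
        raise PlantingError("insertion position outside template")
    array = motif * copies
    new_seq = sequence[:position] + array + sequence[position:]
    truth = {
        "type": "microsatellite",
        "start": position,
        "end": position + len(array),
        "motif": motif,
        "copies": copies,
    }
    return new_seq, truth


def plant_te_insertion(
    sequence: str, position: int, repeat_id: str, te_seq: str
) -> tuple[str, dict]:
    """Insert a transposable-element copy at ``position``."""
    if not 0 <= position <= len(sequence):
        raise PlantingError("insertion position outside template")
    new_seq = sequence[:position] + te_seq + sequence[position:]
    truth = {
        "type": "te",
        "start": position,
        "end": position + len(te_seq),
        "repeat_id": repeat_id,
    }
    return new_seq, truth


# ---------------------------------------------------------------------------
# World construction
# ---------------------------------------------------------------------------

_DEFAULT_REPEATS = [
    # (repeat_id, family, length) -- RepBase-style records; sequences are
    # synthetic stand-ins generated per seed, ids/families follow the
    # elements most often seen in squamate venom-gland libraries.
    ("BovB", "RTE", 1100),
    ("CR1_HS", "CR1", 900),
    ("LINE2_CH1", "L2", 1000),
    ("HAT3_MD", "hAT", 600),
    ("Tc1-3_Xt", "TcMar-Tc1", 500),
]


def _make_base_template(rng, tid, class_label, in_reference=True):
    """Random transcript with a CDS (for annotatable classes) and UTRs."""
    if class_label == "unknown":
        length = int(rng.integers(900, 2200))
        return TemplateSpec(tid, class_label, _random_seq(rng, length), None, None, 1.0,
                            in_reference=False)
    utr5 = int(rng.integers(30, 90))
    cds_len = int(rng.integers(200, 500)) * 3
    utr3 = int(rng.integers(200, 500))
    seq = _random_seq(rng, utr5 + cds_len + utr3)
    return TemplateSpec(tid, class_label, seq, utr5, utr5 + cds_len, 1.0,
                        in_reference=in_reference)


def build_world(config: GeneratorConfig, seed: int | None = None) -> SyntheticWorld:
    """Deterministically build templates, references, repeats and vectors."""
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))

    repeat_library = [(rid, _random_seq(rng, n)) for rid, _, n in _DEFAULT_REPEATS]
    repeat_families = {rid: fam for rid, fam, _ in _DEFAULT_REPEATS}
    repeat_seqs = dict(repeat_library)
    vectors = [("pVEC1_synthetic", _random_seq(rng, 180))]

    templates: dict[str, TemplateSpec] = {}
    groups = list(TOXIN_CLASSES) + ["non_toxin", "unknown"]
    for group in groups:
        n = config.template_counts.get(group, 0)
        for i in range(n):
            tid = f"TPL_{_CLASS_CODES[group]}{i:02d}"
            templates[tid] = _make_base_template(rng, tid, group)

    features: list[dict] = []
    snp_loci: list[dict] = []
    indel_loci: list[dict] = []

    if config.plant_default_features:
        _plant_default_features(
            config, rng, templates, repeat_seqs, features, snp_loci, indel_loci
        )

    # abundance weights within each sampling group (Dirichlet, fixed seed)
    for group in groups:
        members = sorted(t for t in templates if templates[t].class_label == group)
        if not members:
            continue
        w = rng.dirichlet(np.full(len(members), 1.5))
        # skewed but floored: every cloned species is expressed, so every
        # planted feature is observable at sufficient library depth
        w = 0.3 / len(members) + 0.7 * w
        for tid, wi in zip(members, w):
            templates[tid].abundance_weight = float(wi)

    return SyntheticWorld(
        templates=templates,
        repeat_library=repeat_library,
        repeat_families=repeat_families,
        vectors=vectors,
        features=features,
        snp_loci=snp_loci,
        indel_loci=indel_loci,
    )


def _plant_default_features(config, rng, templates, repeat_seqs, features,
                            snp_loci, indel_loci):
    """The default planted-feature panel (SNPs, indels, SSRs, TEs, IRs)."""

    def _tag(tid, rec):
        rec = dict(rec, template=tid)
        features.append(rec)
        templates[tid].planted_features.append(rec)
        return rec

    # --- pure-TE transcripts (unknown group, >90% TE coverage) ----------
    te_choices = ["BovB", "CR1_HS", "LINE2_CH1", "BovB", "CR1_HS"]
    for i in range(config.n_pure_te_templates):
        rid = te_choices[i % len(te_choices)]
        tid = f"TPL_TEU{i:02d}"
        flank5 = _random_seq(rng, int(rng.integers(20, 50)))
        flank3 = _random_seq(rng, int(rng.integers(100, 140)))
        seq = flank5 + repeat_seqs[rid] + flank3
        templates[tid] = TemplateSpec(tid, "unknown", seq, None, None, 1.0,
                                      in_reference=False)
        _tag(tid, {"type": "te", "start": len(flank5),
                   "end": len(flank5) + len(repeat_seqs[rid]), "repeat_id": rid})

    # --- TE-host chimeric transcripts (non_toxin group) -----------------
    # Hosts are reference-only records (the host gene is known to the
    # databases but not independently expressed in this library), and the
    # fused TE segments are disjoint from the pure-TE elements so repeats
    # cannot bridge unrelated transcripts during assembly.
    te_segments = [("HAT3_MD", 0, 250), ("Tc1-3_Xt", 0, 250), ("HAT3_MD", 300, 550)]
    for i in range(config.n_chimera_templates):
        host = f"TPL_HREF{i:02d}"
        templates[host] = _make_base_template(rng, host, "non_toxin")
        templates[host].sampled = False
        rid, s0, s1 = te_segments[i % len(te_segments)]
        te = repeat_seqs[rid][s0:s1]
        hseq = templates[host].sequence
        frag_len = min(700, len(hseq))
        frag = hseq[:frag_len]
        tid = f"TPL_CHI{i:02d}"
        seq = frag + te
        templates[tid] = TemplateSpec(tid, "non_toxin", seq, None, None, 1.0,
                                      in_reference=False, host_id=host)
        _tag(tid, {"type": "te", "start": frag_len, "end": frag_len + len(te),
                   "repeat_id": rid})
        _tag(tid, {"type": "chimera", "te_start": frag_len,
                   "te_end": frag_len + len(te), "repeat_id": rid, "host_id": host})

    # --- inverted repeats ------------------------------------------------
    ir_targets = []
    bpps = sorted(t for t in templates if templates[t].class_label == "BPP/CNP")
    if bpps:
        ir_targets.append((bpps[0], 132, 183, 0.0))
    unks = sorted(t for t in templates if templates[t].class_label == "unknown"
                  and not t.startswith("TPL_TEU"))
    if unks:
        ir_targets.append((unks[0], 60, 40, 0.03))
    for tid, arm, spacer, mrate in ir_targets:
        t = templates[tid]
        pos = len(t.sequence) - 200 if t.cds_end is None else min(
            t.cds_end + 30, len(t.sequence))
        t.sequence, rec = plant_inverted_repeat(t.sequence, pos, arm, spacer, mrate, rng)
        _tag(tid, rec)

    # --- microsatellites -------------------------------------------------
    ssr_plan = [("A", 14), ("AG", 9), ("CT", 8), ("AGC", 6), ("AAGG", 5), ("ACTGG", 4)]
    ssr_hosts = []
    plain_hosts = sorted(t for t in templates
                         if templates[t].class_label == "non_toxin"
                         and templates[t].sampled and not t.startswith("TPL_CHI"))
    ssr_hosts += plain_hosts[3:5]
    ssr_hosts += unks[1:3]
    pla = sorted(t for t in templates if templates[t].class_label == "PLA2")
    ssr_hosts += pla[:1]
    ssr_hosts += [t for t in sorted(templates) if t.startswith("TPL_TEU")][:1]
    for (motif, copies), tid in zip(ssr_plan, ssr_hosts):
        t = templates[tid]
        if t.cds_end is not None:
            pos = int(rng.integers(t.cds_end + 20, len(t.sequence) - 20))
        elif tid.startswith("TPL_TEU"):
            # in the 3' flank, clear of both the TE and the rarely-sampled tail
            pos = len(t.sequence) - 60
        else:
            pos = int(rng.integers(len(t.sequence) - 120, len(t.sequence) - 40))
        t.sequence, rec = plant_microsatellite(t.sequence, pos, motif, copies)
        _tag(tid, rec)

    # --- SNP loci (polymorphic sites, minor-allele frequency 0.5) -------
    mets = sorted(t for t in templates if templates[t].class_label == "metalloproteinase")
    snp_hosts = mets[:3] + pla[:1] + plain_hosts[:2]
    k = 0
    for tid in snp_hosts:
        t = templates[tid]
        for _ in range(2):
            pos = int(rng.integers(t.cds_start + 10, t.cds_end - 10))
            ref = t.sequence[pos]
            alt = [c for c in "ACGT" if c != ref][rng.integers(0, 3)]
            rec = {"type": "snp", "locus_id": f"SNP{k:03d}", "position": pos,
                   "ref": ref, "alt": alt, "maf": 0.5}
            _tag(tid, rec)
            snp_loci.append(dict(rec, template=tid))
            k += 1

    # --- indel loci (short deletions in 3'UTRs) --------------------------
    k = 0
    for tid in mets[3:5] + snp_hosts[-2:]:
        t = templates[tid]
        dlen = int(rng.integers(1, 3))
        pos = int(rng.integers(t.cds_end + 30, len(t.sequence) - 30))
        rec = {"type": "indel", "locus_id": f"IND{k:03d}", "position": pos,
               "length": dlen, "maf": 0.5}
        _tag(tid, rec)
        indel_loci.append(dict(rec, template=tid))
        k += 1


def make_reference_collections(config: GeneratorConfig, seed: int | None = None):
    """(reference records, repeat records, vector records) for a config.

    Reference records are ``(id, sequence, description)`` triples with
    class labels and CDS coordinates in the description; repeat and vector
    records are ``(id, sequence)`` pairs.  Deterministic given the seed.
    """
    world = build_world(config, seed)
    return world.reference_records(), list(world.repeat_library), list(world.vectors)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class ReadTruth:
    template_id: str
    class_label: str
    plate: int
    strand: str
    tpl_start: int
    tpl_end: int
    clean_length: int
    vector_len: int
    polya_len: int
    alleles: dict = field(default_factory=dict)  # locus_id -> 0 (ref) / 1 (alt)


@dataclass
class GroundTruth:
    """Complete registry of what was generated and what was planted."""

    reads: dict  # read_id -> ReadTruth
    features: list  # planted features, template coordinates
    template_classes: dict  # template_id -> class label
    template_hosts: dict  # chimera template -> host reference id
    expected: dict  # configured mixture parameters

    def to_json(self, path: str | Path) -> None:
        payload = {
            "reads": {rid: asdict(rt) for rid, rt in self.reads.items()},
            "features": self.features,
            "template_classes": self.template_classes,
            "template_hosts": self.template_hosts,
            "expected": self.expected,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        reads = {rid: ReadTruth(**rt) for rid, rt in payload["reads"].items()}
        return cls(reads, payload["features"], payload["template_classes"],
                   payload["template_hosts"], payload["expected"])


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------


def _apply_alleles(world, tpl, a, b, rng):
    """Window of a template with per-read planted alleles applied.

    Returns (sequence, alleles dict).  Deletions shrink the window; SNP
    substitutions replace single bases.
    """
    seq = tpl.sequence[a:b]
    alleles = {}
    edits = []
    for rec in tpl.planted_features:
        if rec["type"] == "snp" and a <= rec["position"] < b:
            take_alt = rng.random() < rec["maf"]
            alleles[rec["locus_id"]] = int(take_alt)
            if take_alt:
                edits.append(("sub", rec["position"] - a, rec["alt"]))
        elif rec["type"] == "indel" and a <= rec["position"] < b - rec["length"]:
            take_alt = rng.random() < rec["maf"]
            alleles[rec["locus_id"]] = int(take_alt)
            if take_alt:
                edits.append(("del", rec["position"] - a, rec["length"]))
    for kind, pos, arg in sorted(edits, key=lambda e: -e[1]):
        if kind == "sub":
            seq = seq[:pos] + arg + seq[pos + 1:]
        else:
            seq = seq[:pos] + seq[pos + arg:]
    return seq, alleles


def generate_library(
    config: GeneratorConfig,
    world: SyntheticWorld | None = None,
    seed: int | None = None,
) -> tuple[list[Read], GroundTruth]:
    """Generate reads (FASTA+QUAL-ready) and their ground truth.

    Per read: sample class group (toxin / other-hit / unknown), toxin class
    by the configured mixture, template by abundance weight, a window whose
    length follows the post-cleaning length model, planted alleles at their
    configured frequencies, deposition strand, decorations (5' vector
    prefix, 3' polyA tail), substitution errors at ``per_base_error``, and
    a linearly decaying PHRED profile.  Deterministic given the seed.
    """
    seed = config.seed if seed is None else seed
    if world is None:
        world = build_world(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))

    toxin_groups = [c for c in TOXIN_CLASSES if config.toxin_class_mixture.get(c, 0) > 0]
    toxin_probs = np.array([config.toxin_class_mixture[c] for c in toxin_groups])
    toxin_probs = toxin_probs / toxin_probs.sum()

    group_members = {}
    for g in list(TOXIN_CLASSES) + ["non_toxin", "unknown"]:
        members = world.group_members(g)
        if members:
            ids, ws = zip(*members)
            w = np.array(ws) / sum(ws)
            group_members[g] = (list(ids), w)
    for g in toxin_groups + ["non_toxin", "unknown"]:
        if g not in group_members:
            raise ValueError(f"no templates available for class {g}")

    lengths = config.length_model.sample(rng, config.n_reads)
    deco = config.decoration_model
    p_toxin = config.toxin_fraction_of_total
    p_other_hit = config.hit_fraction_of_total - p_toxin

    bases = np.array(list("ACGT"))
    reads: list[Read] = []
    truth_reads: dict[str, ReadTruth] = {}
    for i in range(config.n_reads):
        u = rng.random()
        if u < p_toxin:
            cls = toxin_groups[rng.choice(len(toxin_groups), p=toxin_probs)]
        elif u < p_toxin + p_other_hit:
            cls = "non_toxin"
        else:
            cls = "unknown"
        ids, w = group_members[cls]
        tpl = world.templates[ids[rng.choice(len(ids), p=w)]]

        length = int(min(lengths[i], len(tpl.sequence)))
        a = int(rng.integers(0, len(tpl.sequence) - length + 1))
        b = a + length
        core, alleles = _apply_alleles(world, tpl, a, b, rng)
        strand = "forward" if rng.random() < 0.5 else "reverse"
        if strand == "reverse":
            core = reverse_complement(core)

        vec_len = 0
        if rng.random() < deco.vector_prob and world.vectors:
            vec_len = int(rng.integers(*deco.vector_len_range))
            vseq = world.vectors[rng.integers(0, len(world.vectors))][1]
            vstart = int(rng.integers(0, max(1, len(vseq) - vec_len + 1)))
            prefix = vseq[vstart:vstart + vec_len]
            vec_len = len(prefix)
        else:
            prefix = ""
        polya_len = 0
        if rng.random() < deco.polya_prob:
            polya_len = int(rng.integers(*deco.polya_len_range))
        seq = prefix + core + "A" * polya_len

        # substitution errors over the whole read
        arr = np.array(list(seq))
        err = rng.random(len(arr)) < config.per_base_error
        if err.any():
            idx = np.flatnonzero(err)
            shift = rng.integers(1, 4, idx.size)
            codes = {"A": 0, "C": 1, "G": 2, "T": 3}
            for j, s in zip(idx, shift):
                arr[j] = bases[(codes.get(arr[j], 0) + s) % 4]
            seq = "".join(arr)

        pos = np.arange(len(seq))
        q = deco.quality_start - deco.quality_slope * pos
        q = q + rng.normal(0.0, deco.quality_jitter_sd, len(seq))
        qual = tuple(int(x) for x in np.clip(np.rint(q), deco.quality_floor, 60))

        plate = int(rng.integers(1, config.n_plates + 1))
        rid = f"EST{i:05d}"
        reads.append(Read(id=rid, seq=seq, qual=qual, plate=plate))
        truth_reads[rid] = ReadTruth(
            template_id=tpl.template_id, class_label=tpl.class_label, plate=plate,
            strand=strand, tpl_start=a, tpl_end=b, clean_length=len(core),
            vector_len=vec_len, polya_len=polya_len, alleles=alleles,
        )

    expected = {
        "toxin_fraction_of_total": config.toxin_fraction_of_total,
        "hit_fraction_of_total": config.hit_fraction_of_total,
        "toxin_class_mixture": dict(config.toxin_class_mixture),
        "mean_clean_length": config.length_model.mean,
    }
    truth = GroundTruth(
        reads=truth_reads,
        features=list(world.features),
        template_classes={t.template_id: t.class_label for t in world.templates.values()},
        template_hosts={t.template_id: t.host_id for t in world.templates.values()
                        if t.host_id},
        expected=expected,
    )
    return reads, truth
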