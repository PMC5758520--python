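"""Synthetic isolate cohorts with planted, ledgered ground truth.

The generator emulates the statistical structure the downstream analysis
assumes for a within-subspecies bacterial cohort sampled across the human
lifespan:

* a shared single-copy core genome plus dispensable gene families whose
  per-strain carriage probability depends on host age through a logistic
  model ``p(age) = sigmoid(beta0 + beta1 * age/10)``;
* family-clonal strains — near-identical genome copies planted in members
  of the same household, with per-site substitution divergence far below
  the between-strain background — including one three-generation chain;
* CRISPR repeat-spacer arrays (identical direct repeats, globally unique
  spacers) inserted at recorded coordinates, with optional deletion of an
  internal spacer block in transmitted clones.

Every planted signal is recorded exactly once in a :class:`TruthLedger`
so that recovery can be scored without re-deriving the truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .io_formats import (
    DEFAULT_SEGMENTATION,
    AgeSegmentation,
    StrainRecord,
    write_fasta,
    write_metadata,
)

__all__ = [
    "ConfigError",
    "PlanError",
    "PlacementError",
    "CrisprPlan",
    "FamilyPlanEntry",
    "CarriageParams",
    "CohortConfig",
    "FamilyTruth",
    "ArrayTruth",
    "TruthLedger",
    "Cohort",
    "simulate_cohort",
    "plant_crispr_arrays",
    "plant_transmissions",
    "simulate_presence_only",
    "paper_profile",
    "mini_profile",
    "write_cohort",
    "COHORT_GENOME_COUNTS",
    "COHORT_SUBJECT_COUNTS",
]


class ConfigError(ValueError):
    """Infeasible cohort configuration."""


class PlanError(ValueError):
    """Inconsistent family/transmission plan."""


class PlacementError(ValueError):
    """A planted feature does not fit in its target contig."""


# Per-segment isolate counts of the emulated cohort design (sums to 113).
COHORT_GENOME_COUNTS: dict[str, int] = {
    "Preweaning": 5,
    "Weaning": 5,
    "weaned-3": 11,
    "4-9 years old": 7,
    "10-19 years old": 9,
    "20-29 years old": 7,
    "30-39 years old": 12,
    "40-49 years old": 9,
    "50-59 years old": 10,
    "60-69 years old": 10,
    "70-79 years old": 11,
    "80-89 years old": 12,
    "90-99 years old": 5,
    "100-104 years old": 0,
}

# Per-segment subject counts of the source cross-sectional survey (sums to 453).
COHORT_SUBJECT_COUNTS: dict[str, int] = {
    "Preweaning": 13,
    "Weaning": 12,
    "weaned-3": 22,
    "4-9 years old": 17,
    "10-19 years old": 10,
    "20-29 years old": 42,
    "30-39 years old": 117,
    "40-49 years old": 37,
    "50-59 years old": 34,
    "60-69 years old": 42,
    "70-79 years old": 31,
    "80-89 years old": 51,
    "90-99 years old": 19,
    "100-104 years old": 6,
}

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOP_CODON_IDX = np.array([48, 50, 56])  # TAA, TAG, TGA with A,C,G,T = 0..3
_SENSE_CODONS = np.array(
    [
        [a, b, c]
        for a in range(4)
        for b in range(4)
        for c in range(4)
        if (a * 16 + b * 4 + c) not in (48, 50, 56)
    ],
    dtype=np.uint8,
)


@dataclass(frozen=True)
class CarriageParams:
    """Logistic carriage model for one dispensable family.

    ``beta1`` is the log-odds change per decade of host age; ``direction``
    is the planted enrichment label (``younger``/``older``/``none``).
    """

    beta0: float
    beta1: float
    direction: str = "none"

    def prob(self, age: float | np.ndarray) -> np.ndarray:
        z = self.beta0 + self.beta1 * np.asarray(age, dtype=float) / 10.0
        return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class FamilyPlanEntry:
    """One household: member host ages and which members form a clone chain.

    Members whose flag is ``True`` form a transmission chain in list order:
    the first flagged member is the donor founder, each later flagged member
    is a near-identical clone of the previous flagged member.  Unflagged
    members receive independent genomes (the within-family negatives).
    """

    family_id: str
    member_ages: tuple[float, ...]
    transmitted_clone_flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.member_ages) != len(self.transmitted_clone_flags):
            raise PlanError(f"{self.family_id}: ages/flags length mismatch")
        n_flagged = sum(self.transmitted_clone_flags)
        if n_flagged == 1:
            raise PlanError(
                f"{self.family_id}: a single flagged member has no donor "
                "(chains need at least two flagged members)"
            )


@dataclass(frozen=True)
class CrisprPlan:
    """Placement plan for repeat-spacer arrays."""

    n_strains_with_arrays: int = 0
    repeat_length: int = 36
    spacer_length_range: tuple[int, int] = (32, 40)
    spacers_per_array_range: tuple[int, int] = (24, 58)
    clone_spacer_deletion_prob: float = 0.6
    clone_deletion_block_range: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        if not (23 <= self.repeat_length <= 55):
            raise ConfigError("repeat length must be within [23, 55]")
        lo, hi = self.spacer_length_range
        if not (20 <= lo <= hi <= 72):
            raise ConfigError("spacer length range must be within [20, 72]")


@dataclass
class CohortConfig:
    """Full specification of a synthetic cohort.

    ``genes_per_genome_target`` is the expected gene count per genome; the
    neutral dispensable baseline is solved so the cohort mean lands within
    ~10% of it.  All randomness flows from ``seed`` through named substreams
    (ages, sequences, carriage, crispr, clones).
    """

    n_strains: int = 30
    n_core_families: int = 180
    n_dispensable_families: int = 300
    genes_per_genome_target: int = 300
    segment_counts: dict[str, int] = field(default_factory=dict)
    segmentation: AgeSegmentation = DEFAULT_SEGMENTATION
    n_younger_enriched: int = 7
    n_older_enriched: int = 3
    carriage_model: list[CarriageParams] | None = None
    protein_length_range: tuple[int, int] = (150, 600)
    strain_divergence: float = 0.01
    clone_divergence: float = 1e-4
    family_plan: tuple[FamilyPlanEntry, ...] = ()
    crispr_plan: CrisprPlan = field(default_factory=CrisprPlan)
    n_contigs: int = 4
    n_multicopy_core: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_strains,
            self.n_core_families,
            self.n_dispensable_families,
            self.genes_per_genome_target,
        ) <= 0:
            raise ConfigError("all cohort counts must be positive")
        if not (0.0 <= self.clone_divergence <= 0.005):
            raise ConfigError("clone_divergence must be in [0, 0.005]")
        if self.n_core_families >= self.genes_per_genome_target:
            raise ConfigError(
                "core families alone exceed the per-genome gene target"
            )
        if self.segment_counts and sum(self.segment_counts.values()) != self.n_strains:
            raise ConfigError("segment_counts must sum to n_strains")
        if self.n_younger_enriched + self.n_older_enriched > self.n_dispensable_families:
            raise ConfigError("more enriched families than dispensable families")

    def to_yaml(self, path: str | Path) -> Path:
        d = dataclasses.asdict(self)
        d["segmentation"] = [
            [s.label, s.min_age, s.max_age] for s in self.segmentation.segments
        ]
        d["family_plan"] = [
            {
                "family_id": e.family_id,
                "member_ages": list(e.member_ages),
                "transmitted_clone_flags": list(e.transmitted_clone_flags),
            }
            for e in self.family_plan
        ]
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
        return path


# ---------------------------------------------------------------------------
# Truth ledger
# ---------------------------------------------------------------------------

@dataclass
class FamilyTruth:
    gf_id: str
    kind: str  # core | dispensable
    params: CarriageParams
    gene_ids: set[str] = field(default_factory=set)
    multicopy_strains: set[str] = field(default_factory=set)

    @property
    def direction(self) -> str:
        return self.params.direction


@dataclass
class ArrayTruth:
    strain_id: str
    contig_id: str
    start: int  # 0-based half-open, final contig coordinates
    end: int
    repeat: str
    spacers: list[str]


@dataclass
class TruthLedger:
    """Ground truth for every planted signal of one cohort."""

    families: dict[str, FamilyTruth] = field(default_factory=dict)
    arrays: dict[str, ArrayTruth] = field(default_factory=dict)
    transmitted_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    clone_strains: set[str] = field(default_factory=set)
    segment_rates: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def single_copy_core(self) -> set[str]:
        return {
            f.gf_id
            for f in self.families.values()
            if f.kind == "core" and not f.multicopy_strains
        }

    def enriched(self, direction: str) -> set[str]:
        return {
            f.gf_id for f in self.families.values() if f.direction == direction
        }

    def family_gene_sets(self) -> list[frozenset[str]]:
        return [frozenset(f.gene_ids) for f in self.families.values()]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "truth_families.tsv", "w", newline="\n") as fh:
            fh.write("gf_id\tkind\tbeta0\tbeta1\tdirection\tn_genes\tgene_ids\n")
            for f in self.families.values():
                fh.write(
                    f"{f.gf_id}\t{f.kind}\t{f.params.beta0:.6g}\t{f.params.beta1:.6g}"
                    f"\t{f.direction}\t{len(f.gene_ids)}\t{','.join(sorted(f.gene_ids))}\n"
                )
        with open(outdir / "truth_arrays.tsv", "w", newline="\n") as fh:
            fh.write("strain_id\tcontig_id\tstart\tend\trepeat\tspacers\n")
            for a in self.arrays.values():
                fh.write(
                    f"{a.strain_id}\t{a.contig_id}\t{a.start}\t{a.end}\t{a.repeat}"
                    f"\t{','.join(a.spacers)}\n"
                )
        with open(outdir / "truth_transmissions.tsv", "w", newline="\n") as fh:
            fh.write("strain_a\tstrain_b\tfamily_id\n")
            for a, b, fam in self.transmitted_pairs:
                fh.write(f"{a}\t{b}\t{fam}\n")


# ---------------------------------------------------------------------------
# Internal genome representation
# ---------------------------------------------------------------------------

@dataclass
class _Gene:
    gene_id: str
    gf_id: str
    cds: np.ndarray  # uint8 codes 0..3


@dataclass
class _PlantedArray:
    contig_index: int
    offset: int  # position in the raw (pre-insertion) contig
    repeat: str
    spacers: list[str]


@dataclass
class _Genome:
    strain_id: str
    subject_id: str
    family_id: str
    age_years: float
    sex: str
    age_segment: str
    genes: list[_Gene] = field(default_factory=list)
    arrays: list[_PlantedArray] = field(default_factory=list)


@dataclass
class Cohort:
    """In-flight cohort: genomes plus the generating configuration."""

    config: CohortConfig
    genomes: list[_Genome]
    plan_members: dict[str, list[str]] = field(default_factory=dict)

    def genome(self, strain_id: str) -> _Genome:
        for g in self.genomes:
            if g.strain_id == strain_id:
                return g
        raise KeyError(strain_id)

    # -- materialization ---------------------------------------------------

    def to_records(self, ledger: TruthLedger | None = None) -> list[StrainRecord]:
        """Materialize contigs/proteomes; optionally fill ledger coordinates."""
        from Bio.Seq import Seq

        records = []
        for g in self.genomes:
            n_contigs = max(1, min(self.config.n_contigs, len(g.genes)))
            per = -(-len(g.genes) // n_contigs)
            contigs: list[tuple[str, str]] = []
            proteins: list[tuple[str, str]] = []
            cds_records: list[tuple[str, str]] = []
            raw_parts: list[list[np.ndarray]] = [[] for _ in range(n_contigs)]
            for k, gene in enumerate(g.genes):
                raw_parts[min(k // per, n_contigs - 1)].append(gene.cds)
                nt = _decode(gene.cds)
                cds_records.append((gene.gene_id, nt))
                aa = str(Seq(nt).translate())
                proteins.append((gene.gene_id, aa))
            for ci in range(n_contigs):
                raw = _decode(np.concatenate(raw_parts[ci])) if raw_parts[ci] else ""
                raw_len = len(raw)
                cid = f"{g.strain_id}_c{ci + 1}"
                inserts = sorted(
                    (a for a in g.arrays if a.contig_index == ci),
                    key=lambda a: a.offset,
                )
                shift = 0
                for arr in inserts:
                    block = _array_sequence(arr.repeat, arr.spacers)
                    if arr.offset > raw_len:
                        raise PlacementError(
                            f"{cid}: array offset {arr.offset} beyond contig end"
                        )
                    pos = arr.offset + shift
                    raw = raw[:pos] + block + raw[pos:]
                    if ledger is not None:
                        ledger.arrays[g.strain_id] = ArrayTruth(
                            strain_id=g.strain_id,
                            contig_id=cid,
                            start=pos,
                            end=pos + len(block),
                            repeat=arr.repeat,
                            spacers=list(arr.spacers),
                        )
                    shift += len(block)
                contigs.append((cid, raw))
            records.append(
                StrainRecord(
                    strain_id=g.strain_id,
                    subject_id=g.subject_id,
                    family_id=g.family_id,
                    age_years=g.age_years,
                    sex=g.sex,
                    age_segment=g.age_segment,
                    proteins=proteins,
                    contigs=contigs,
                    cds=cds_records,
                )
            )
        return records


def _decode(arr: np.ndarray) -> str:
    return _NT[arr].tobytes().decode()


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 255, np.uint8)
    for i, c in enumerate("ACGT"):
        lut[ord(c)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _array_sequence(repeat: str, spacers: Sequence[str]) -> str:
    parts = [repeat]
    for sp in spacers:
        parts.append(sp)
        parts.append(repeat)
    return "".join(parts)


def _random_cds(n_aa: int, rng: np.random.Generator) -> np.ndarray:
    codons = _SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS), n_aa)]
    return codons.reshape(-1)


def _mutate_cds(cds: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution avoiding the creation of internal stop codons."""
    out = cds.copy()
    if rate <= 0:
        return out
    mask = rng.random(out.shape[0]) < rate
    n = int(mask.sum())
    if n == 0:
        return out
    out[mask] = (out[mask] + rng.integers(1, 4, n).astype(np.uint8)) % 4
    codons = out.reshape(-1, 3).astype(np.int16)
    idx = codons[:, 0] * 16 + codons[:, 1] * 4 + codons[:, 2]
    stop = np.isin(idx, _STOP_CODON_IDX)
    if stop.any():
        orig = cds.reshape(-1, 3)
        codons[stop] = orig[stop]
        out = codons.astype(np.uint8).reshape(-1)
    return out


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _substreams(seed: int) -> dict[str, np.random.Generator]:
    names = ["ages", "sequences", "carriage", "crispr", "clones"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _sample_ages(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    seg = config.segmentation
    counts = config.segment_counts or _proportional_counts(
        config.n_strains, config.segmentation
    )
    ages = []
    for s in seg.segments:
        k = counts.get(s.label, 0)
        hi = min(s.max_age, 104.0)
        ages.extend(rng.uniform(s.min_age, hi, k))
    ages = np.array(ages)
    if ages.shape[0] != config.n_strains:
        raise ConfigError("segment counts do not cover n_strains")
    return ages


def _proportional_counts(n: int, seg: AgeSegmentation) -> dict[str, int]:
    base = COHORT_GENOME_COUNTS
    labels = seg.labels
    weights = np.array([base.get(l, 1) for l in labels], dtype=float)
    weights /= weights.sum()
    raw = weights * n
    counts = np.floor(raw).astype(int)
    rema = raw - counts
    for i in np.argsort(-rema)[: n - counts.sum()]:
        counts[i] += 1
    return dict(zip(labels, counts.tolist()))


def _build_carriage_model(
    config: CohortConfig, ages: np.ndarray, rng: np.random.Generator
) -> list[CarriageParams]:
    if config.carriage_model is not None:
        if len(config.carriage_model) != config.n_dispensable_families:
            raise ConfigError("carriage_model length must equal n_dispensable_families")
        return list(config.carriage_model)
    n_y = config.n_younger_enriched
    n_o = config.n_older_enriched
    n_neutral = config.n_dispensable_families - n_y - n_o
    model: list[CarriageParams] = []
    for _ in range(n_y):
        model.append(
            CarriageParams(
                beta0=float(rng.uniform(1.5, 2.5)),
                beta1=float(rng.uniform(-2.2, -1.2)),
                direction="younger",
            )
        )
    for _ in range(n_o):
        model.append(
            CarriageParams(
                beta0=float(rng.uniform(-3.5, -2.5)),
                beta1=float(rng.uniform(0.6, 1.0)),
                direction="older",
            )
        )
    mean_enriched = sum(float(p.prob(ages).mean()) for p in model)
    need = config.genes_per_genome_target - config.n_core_families - mean_enriched
    if n_neutral > 0:
        mu = need / n_neutral
        if not (0.02 < mu < 0.98):
            raise ConfigError(
                f"infeasible gene target: neutral carriage mean {mu:.3f} "
                "outside (0.02, 0.98)"
            )
        means = np.clip(mu + rng.normal(0.0, 0.10, n_neutral), 0.06, 0.94)
        means += mu - means.mean()
        means = np.clip(means, 0.05, 0.95)
        for mval in means:
            model.append(
                CarriageParams(beta0=float(np.log(mval / (1 - mval))), beta1=0.0)
            )
    return model


def simulate_cohort(config: CohortConfig) -> tuple[list[StrainRecord], TruthLedger]:
    """Generate a full cohort plus its truth ledger.

    Deterministic given ``config.seed``: identical configs produce
    byte-identical FASTA/metadata outputs.
    """
    cohort, ledger = build_base_cohort(config)
    rngs = _substreams(config.seed)
    if config.crispr_plan.n_strains_with_arrays > 0:
        plant_crispr_arrays(cohort, ledger, config.crispr_plan, rngs["crispr"])
    if config.family_plan:
        plant_transmissions(cohort, ledger, config.family_plan, rngs["clones"])
    records = cohort.to_records(ledger)
    _fill_family_gene_sets(cohort, ledger)
    return records, ledger


def build_base_cohort(config: CohortConfig) -> tuple[Cohort, TruthLedger]:
    """Generate the pre-planting cohort: genomes with age-dependent carriage."""
    rngs = _substreams(config.seed)
    ages = np.sort(_sample_ages(config, rngs["ages"]))
    n = config.n_strains
    width = max(3, len(str(n)))
    strain_ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    sexes = ["M" if v < 0.5 else "F" for v in rngs["ages"].random(n)]

    # ancestral families
    rng_seq = rngs["sequences"]
    gf_ids = [f"TGF{i + 1:04d}" for i in range(config.n_core_families)] + [
        f"TGFD{i + 1:04d}" for i in range(config.n_dispensable_families)
    ]
    kinds = ["core"] * config.n_core_families + [
        "dispensable"
    ] * config.n_dispensable_families
    lo, hi = config.protein_length_range
    lengths = rng_seq.integers(lo, hi + 1, len(gf_ids))
    ancestral = [_random_cds(int(L), rng_seq) for L in lengths]

    model = _build_carriage_model(config, ages, rngs["carriage"])
    params_by_gf: dict[str, CarriageParams] = {}
    for i, gf in enumerate(gf_ids):
        if kinds[i] == "core":
            params_by_gf[gf] = CarriageParams(beta0=np.inf, beta1=0.0)
        else:
            params_by_gf[gf] = model[i - config.n_core_families]

    ledger = TruthLedger()
    for gf, kind in zip(gf_ids, kinds):
        ledger.families[gf] = FamilyTruth(gf_id=gf, kind=kind, params=params_by_gf[gf])

    # true per-segment carriage rates (expected, from the logistic model)
    seg = config.segmentation
    seg_of_age = [seg.assign(a) for a in ages]
    for gf, kind in zip(gf_ids, kinds):
        p = params_by_gf[gf]
        rates = {}
        for s in seg.segments:
            idx = [i for i, l in enumerate(seg_of_age) if l == s.label]
            if idx:
                rates[s.label] = (
                    1.0 if kind == "core" else float(np.mean(p.prob(ages[idx])))
                )
        ledger.segment_rates[gf] = rates

    rng_carriage = rngs["carriage"]
    genomes: list[_Genome] = []
    n_disp = config.n_dispensable_families
    carry_probs = np.vstack(
        [model[j].prob(ages) for j in range(n_disp)]
    )  # families x strains
    carried_mask = rng_carriage.random(carry_probs.shape) < carry_probs

    # multicopy owners must stay outside clone chains: a clone's genome is
    # replaced wholesale, which would silently drop (or copy) the duplicate
    chained = _chain_members_by_age(strain_ids, ages, config.family_plan)
    ownable = [s for s in strain_ids if s not in chained]
    multicopy_assign: dict[str, str] = {}
    for k in range(min(config.n_multicopy_core, config.n_core_families, len(ownable))):
        multicopy_assign[gf_ids[k]] = ownable[k]

    for si, sid in enumerate(strain_ids):
        g = _Genome(
            strain_id=sid,
            subject_id=f"P{si + 1:0{width}d}",
            family_id="",
            age_years=float(ages[si]),
            sex=sexes[si],
            age_segment=seg_of_age[si],
        )
        carried = list(range(config.n_core_families)) + [
            config.n_core_families + j for j in range(n_disp) if carried_mask[j, si]
        ]
        gi = 0
        for fam_idx in carried:
            gi += 1
            cds = _mutate_cds(ancestral[fam_idx], config.strain_divergence, rng_seq)
            g.genes.append(_Gene(f"{sid}_g{gi:04d}", gf_ids[fam_idx], cds))
        for gf, owner in multicopy_assign.items():
            if owner == sid:
                gi += 1
                fam_idx = gf_ids.index(gf)
                cds = _mutate_cds(
                    ancestral[fam_idx], config.strain_divergence, rng_seq
                )
                g.genes.append(_Gene(f"{sid}_g{gi:04d}", gf, cds))
                ledger.families[gf].multicopy_strains.add(sid)
        genomes.append(g)

    return Cohort(config=config, genomes=genomes), ledger


def _fill_family_gene_sets(cohort: Cohort, ledger: TruthLedger) -> None:
    for f in ledger.families.values():
        f.gene_ids.clear()
    for g in cohort.genomes:
        for gene in g.genes:
            ledger.families[gene.gf_id].gene_ids.add(gene.gene_id)


# ---------------------------------------------------------------------------
# Planting operations
# ---------------------------------------------------------------------------

def plant_crispr_arrays(
    cohort: Cohort,
    truth: TruthLedger,
    plan: CrisprPlan,
    rng: np.random.Generator | None = None,
) -> None:
    """Insert one repeat-spacer array per selected strain.

    Strains covered by clone chains inherit the founder's array later (via
    :func:`plant_transmissions`), so founders are always selected and clone
    positions are excluded from the independent draw; the total number of
    array-bearing strains after planting equals ``plan.n_strains_with_arrays``.
    """
    if rng is None:
        rng = _substreams(cohort.config.seed)["crispr"]
    config = cohort.config
    founders: list[str] = []
    chained: set[str] = set()
    member_map = _match_plan_members(cohort, config.family_plan)
    for entry in config.family_plan:
        members = member_map[entry.family_id]
        chain = [m for m, f in zip(members, entry.transmitted_clone_flags) if f]
        if chain:
            founders.append(chain[0])
            chained.update(chain)
    n_extra = plan.n_strains_with_arrays - len(chained)
    if n_extra < 0:
        raise ConfigError(
            "n_strains_with_arrays smaller than the number of clone-chain members"
        )
    eligible = [g.strain_id for g in cohort.genomes if g.strain_id not in chained]
    extra = list(rng.choice(eligible, size=n_extra, replace=False)) if n_extra else []
    used_spacers: set[str] = set()

    def _unique_seq(length: int) -> str:
        while True:
            s = _decode(rng.integers(0, 4, length).astype(np.uint8))
            if s not in used_spacers:
                used_spacers.add(s)
                return s

    for sid in founders + sorted(extra):
        g = cohort.genome(sid)
        repeat = _unique_seq(plan.repeat_length)
        k = int(rng.integers(*plan.spacers_per_array_range, endpoint=True))
        spacers = [
            _unique_seq(int(rng.integers(*plan.spacer_length_range, endpoint=True)))
            for _ in range(k)
        ]
        block_len = (k + 1) * plan.repeat_length + sum(len(s) for s in spacers)
        contig_index = int(rng.integers(0, max(1, min(config.n_contigs, len(g.genes)))))
        contig_len = _raw_contig_length(g, contig_index, config)
        if contig_len < 200:
            raise PlacementError(
                f"{sid}: contig {contig_index} too short to host a "
                f"{block_len} bp array"
            )
        offset = int(rng.integers(100, contig_len - 100))
        g.arrays.append(_PlantedArray(contig_index, offset, repeat, spacers))


def _raw_contig_length(g: _Genome, contig_index: int, config: CohortConfig) -> int:
    n_contigs = max(1, min(config.n_contigs, len(g.genes)))
    per = -(-len(g.genes) // n_contigs)
    total = 0
    for k, gene in enumerate(g.genes):
        if min(k // per, n_contigs - 1) == contig_index:
            total += gene.cds.shape[0]
    return total


def _match_members(
    strain_ids: Sequence[str],
    ages: Sequence[float],
    family_plan: Sequence[FamilyPlanEntry],
) -> dict[str, list[str]]:
    """Map plan member ages to concrete strains (nearest unassigned age)."""
    age_of = dict(zip(strain_ids, ages))
    taken: set[str] = set()
    out: dict[str, list[str]] = {}
    for entry in family_plan:
        members = []
        for target_age in entry.member_ages:
            cands = [s for s in strain_ids if s not in taken]
            if not cands:
                raise PlanError(f"{entry.family_id}: no unassigned strains left")
            best = min(cands, key=lambda s: (abs(age_of[s] - target_age), s))
            taken.add(best)
            members.append(best)
        out[entry.family_id] = members
    return out


def _chain_members_by_age(
    strain_ids: Sequence[str],
    ages: Sequence[float],
    family_plan: Sequence[FamilyPlanEntry],
) -> set[str]:
    """Strains that will belong to a clone chain (founders and clones)."""
    members = _match_members(strain_ids, ages, family_plan)
    out: set[str] = set()
    for entry in family_plan:
        for sid, flag in zip(members[entry.family_id], entry.transmitted_clone_flags):
            if flag:
                out.add(sid)
    return out


def _match_plan_members(
    cohort: Cohort, family_plan: Sequence[FamilyPlanEntry]
) -> dict[str, list[str]]:
    if cohort.plan_members:
        return cohort.plan_members
    out = _match_members(
        [g.strain_id for g in cohort.genomes],
        [g.age_years for g in cohort.genomes],
        family_plan,
    )
    cohort.plan_members = out
    return out


def plant_transmissions(
    cohort: Cohort,
    truth: TruthLedger,
    family_plan: Sequence[FamilyPlanEntry],
    rng: np.random.Generator | None = None,
) -> None:
    """Assign families and convert flagged members into clone chains.

    Each clone's genome is a copy of its donor's, substituted per-site at
    ``clone_divergence`` (so planted pair ANI stays above 99.9%); a clone
    inherits the donor's array and, with the plan's probability, loses a
    contiguous internal block of spacers — the partial-match signature of
    spacer turnover after transmission.
    """
    if rng is None:
        rng = _substreams(cohort.config.seed)["clones"]
    config = cohort.config
    plan = config.crispr_plan
    member_map = _match_plan_members(cohort, family_plan)
    for entry in family_plan:
        members = member_map[entry.family_id]
        for sid in members:
            cohort.genome(sid).family_id = entry.family_id
        chain = [m for m, f in zip(members, entry.transmitted_clone_flags) if f]
        for donor_id, clone_id in zip(chain, chain[1:]):
            donor = cohort.genome(donor_id)
            clone = cohort.genome(clone_id)
            clone.genes = [
                _Gene(
                    f"{clone_id}_g{gi + 1:04d}",
                    gene.gf_id,
                    _mutate_cds(gene.cds, config.clone_divergence, rng),
                )
                for gi, gene in enumerate(donor.genes)
            ]
            clone.arrays = []
            for arr in donor.arrays:
                spacers = list(arr.spacers)
                if (
                    len(spacers) >= 4
                    and rng.random() < plan.clone_spacer_deletion_prob
                ):
                    blo, bhi = plan.clone_deletion_block_range
                    blen = int(rng.integers(blo, bhi + 1))
                    blen = min(blen, len(spacers) - 2)
                    start = int(rng.integers(1, len(spacers) - blen))
                    spacers = spacers[:start] + spacers[start + blen :]
                clone.arrays.append(
                    _PlantedArray(arr.contig_index, arr.offset, arr.repeat, spacers)
                )
            truth.clone_strains.add(clone_id)
        for i in range(len(chain)):
            for j in range(i + 1, len(chain)):
                truth.transmitted_pairs.append((chain[i], chain[j], entry.family_id))


# ---------------------------------------------------------------------------
# Presence-only simulation (statistical calibration)
# ---------------------------------------------------------------------------

def simulate_presence_only(
    ages: np.ndarray,
    model: Sequence[CarriageParams],
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample a strains x families presence matrix from a carriage model only.

    Used for statistical calibration runs where sequences are irrelevant.
    """
    probs = np.vstack([p.prob(ages) for p in model]).T  # strains x families
    return (rng.random(probs.shape) < probs).astype(np.int8)


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def _default_family_plan(full: bool) -> tuple[FamilyPlanEntry, ...]:
    plan = [
        # three-generation chain (infant / mother / grandmother) + one
        # unrelated cohabitant
        FamilyPlanEntry("fam01", (1.0, 36.0, 65.0, 30.0), (True, True, True, False)),
        FamilyPlanEntry("fam02", (28.0, 0.8), (True, True)),
        FamilyPlanEntry("fam03", (52.0, 55.0), (True, True)),
        FamilyPlanEntry("fam04", (5.0, 33.0, 62.0), (False, False, False)),
        FamilyPlanEntry("fam05", (14.0, 48.0, 51.0), (False, False, False)),
    ]
    if full:
        plan += [
            FamilyPlanEntry("fam06", (70.0, 72.0), (False, False)),
            FamilyPlanEntry("fam07", (2.0, 29.0), (False, False)),
            FamilyPlanEntry("fam08", (40.0, 67.0, 90.0), (False, False, False)),
            FamilyPlanEntry("fam09", (0.3, 26.0, 58.0), (False, False, False)),
            FamilyPlanEntry("fam10", (35.0, 38.0, 63.0), (False, False, False)),
        ]
    return tuple(plan)


def paper_profile(seed: int = 0) -> CohortConfig:
    """The 113-strain acceptance fixture.

    Age distribution follows the emulated cohort's genome-count column;
    26 younger- and 9 older-enriched dispensable families mirror the source
    study's enriched/tested proportions; CRISPR arrays are planted in exactly
    50 strains; 5 transmitted pairs (one three-generation chain) and 20
    non-transmitted within-family pairs are planted.
    """
    return CohortConfig(
        n_strains=113,
        n_core_families=120,
        n_dispensable_families=300,
        genes_per_genome_target=240,
        segment_counts=dict(COHORT_GENOME_COUNTS),
        n_younger_enriched=26,
        n_older_enriched=9,
        family_plan=_default_family_plan(full=True),
        crispr_plan=CrisprPlan(n_strains_with_arrays=50),
        seed=seed,
    )


def mini_profile(seed: int = 0) -> CohortConfig:
    """A 30-strain reduction of the acceptance fixture for fast runs."""
    counts = {
        "Preweaning": 1,
        "Weaning": 1,
        "weaned-3": 3,
        "4-9 years old": 2,
        "10-19 years old": 2,
        "20-29 years old": 2,
        "30-39 years old": 3,
        "40-49 years old": 2,
        "50-59 years old": 3,
        "60-69 years old": 3,
        "70-79 years old": 3,
        "80-89 years old": 3,
        "90-99 years old": 2,
        "100-104 years old": 0,
    }
    return CohortConfig(
        n_strains=30,
        n_core_families=60,
        n_dispensable_families=120,
        genes_per_genome_target=100,
        segment_counts=counts,
        n_younger_enriched=10,
        n_older_enriched=4,
        protein_length_range=(120, 400),
        family_plan=_default_family_plan(full=False),
        crispr_plan=CrisprPlan(
            n_strains_with_arrays=12, spacers_per_array_range=(24, 40)
        ),
        seed=seed,
    )


def write_cohort(
    records: Sequence[StrainRecord],
    outdir: str | Path,
    ledger: TruthLedger | None = None,
    config: CohortConfig | None = None,
) -> Path:
    """Write per-strain protein/genome FASTA, metadata TSV, truth and config."""
    outdir = Path(outdir)
    (outdir / "proteins").mkdir(parents=True, exist_ok=True)
    (outdir / "genomes").mkdir(parents=True, exist_ok=True)
    (outdir / "genes").mkdir(parents=True, exist_ok=True)
    for rec in records:
        write_fasta(rec.proteins, outdir / "proteins" / f"{rec.strain_id}.faa")
        write_fasta(rec.contigs, outdir / "genomes" / f"{rec.strain_id}.fna")
        if rec.cds:
            write_fasta(rec.cds, outdir / "genes" / f"{rec.strain_id}.ffn")
    write_metadata(records, outdir / "metadata.tsv")
    if ledger is not None:
        ledger.write(outdir / "truth")
    if config is not None:
        config.to_yaml(outdir / "cohort_config.yaml")
    return outdir
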