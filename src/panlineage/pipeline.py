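"""End-to-end orchestration with deterministic seeding and a manifest.

Stages run in dependency order: synthetic cohort -> orthology -> pan-genome
-> enrichment / CRISPR -> transmission / phylogeny.  Every run writes its
configuration and a manifest with SHA-256 hashes of all result tables, so
re-running with the same config and seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np

from . import (
    age_enrichment,
    core_phylogeny,
    crispr_typing,
    orthology,
    pangenome,
    synthetic_cohort,
    transmission,
)
from .io_formats import StrainRecord, write_matrix_tsv
from .synthetic_cohort import CohortConfig, TruthLedger

logger = logging.getLogger("panlineage")

__all__ = ["PipelineConfig", "PipelineResult", "run_all", "evaluate_against_truth"]


@dataclass
class PipelineConfig:
    """Stage toggles and parameters for one pipeline run."""

    out_dir: Path = Path("panlineage_results")
    profile: str = "mini"  # mini | paper
    seed: int = 0
    cohort: CohortConfig | None = None
    run_crispr: bool = True
    run_phylo: bool = True
    run_primers: bool = False
    n_primer_targets: int = 5
    inflation: float = 2.0
    align_band: int = 32  # diagonal band for the similarity search
    alpha_q: float = 0.2
    fdr_method: str = "storey"
    ani_threshold: float = 99.5
    n_phylo_families: int = 20
    bootstrap_reps: int = 100
    outgroup: str | None = None
    write_cohort_files: bool = True

    def resolve_cohort(self) -> CohortConfig:
        if self.cohort is not None:
            return self.cohort
        if self.profile == "paper":
            return synthetic_cohort.paper_profile(seed=self.seed)
        if self.profile == "mini":
            return synthetic_cohort.mini_profile(seed=self.seed)
        raise ValueError(f"unknown profile {self.profile!r}")


@dataclass
class PipelineResult:
    out_dir: Path
    records: list[StrainRecord]
    ledger: TruthLedger
    families: list[orthology.GeneFamily]
    matrix: pangenome.PresenceMatrix
    single_copy_core: list[str]
    enrichment: list[age_enrichment.EnrichmentResult]
    orf_age: pangenome.SpearmanResult
    arrays: dict[str, list[crispr_typing.CrisprArray]]
    primers: dict[str, crispr_typing.PrimerCandidate | None]
    calls: list[transmission.TransmissionCall]
    tree: core_phylogeny.Tree | None
    manifest: dict[str, Any]


def _stage_seed(base: int, index: int) -> int:
    return int(np.random.SeedSequence([base, index]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> PipelineResult:
    """Run all enabled stages; write result tables and a manifest."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"stages": {}, "seed": config.seed}

    def stage(name):
        logger.info("stage %s ...", name)
        return time.time()

    # --- synthetic cohort -------------------------------------------------
    t = stage("synthetic")
    cohort_cfg = config.resolve_cohort()
    records, ledger = synthetic_cohort.simulate_cohort(cohort_cfg)
    if config.write_cohort_files:
        synthetic_cohort.write_cohort(records, out / "cohort", ledger, cohort_cfg)
    manifest["stages"]["synthetic"] = {
        "n_strains": len(records),
        "mean_genes": float(np.mean([r.n_genes for r in records])),
        "seconds": round(time.time() - t, 2),
    }

    # --- orthology --------------------------------------------------------
    t = stage("orthology")
    params = orthology.AlignParams(band=config.align_band)
    proteomes = {r.strain_id: r.proteins for r in records}
    families, _graph = orthology.build_families(
        proteomes, params, inflation=config.inflation
    )
    orthology.write_families_tsv(families, out / "families.tsv")
    manifest["stages"]["orthology"] = {
        "n_genes": sum(len(p) for p in proteomes.values()),
        "n_families": len(families),
        "seconds": round(time.time() - t, 2),
    }

    # --- pan-genome -------------------------------------------------------
    t = stage("pangenome")
    matrix = pangenome.build_presence_matrix(families, records)
    write_matrix_tsv(
        matrix.presence.to_numpy(),
        matrix.strain_ids,
        matrix.gf_ids,
        out / "matrix.tsv",
    )
    sc_core = pangenome.select_single_copy_core(matrix)
    dendro = pangenome.strain_dendrogram(matrix, distance="covariance")
    (out / "strain_dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    orf_age = pangenome.orf_age_correlation(records)
    manifest["stages"]["pangenome"] = {
        "n_core": len(matrix.core_gfs()),
        "n_dispensable": len(matrix.dispensable_gfs()),
        "n_single_copy_core": len(sc_core),
        "orf_age_rho": round(orf_age.rho, 4),
        "orf_age_p": float(orf_age.p_value),
        "seconds": round(time.time() - t, 2),
    }

    # --- age enrichment ---------------------------------------------------
    t = stage("enrichment")
    enr = age_enrichment.classify_enrichment(
        matrix,
        records,
        cohort_cfg.segmentation,
        alpha_q=config.alpha_q,
        fdr_method=config.fdr_method,
    )
    age_enrichment.results_to_frame(enr).to_csv(
        out / "enrichment.tsv", sep="\t", index=False, lineterminator="\n"
    )
    manifest["stages"]["enrichment"] = {
        "n_tested": len(enr),
        "n_younger": sum(r.direction == "younger" for r in enr),
        "n_older": sum(r.direction == "older" for r in enr),
        "seconds": round(time.time() - t, 2),
    }

    # --- CRISPR -----------------------------------------------------------
    arrays: dict[str, list[crispr_typing.CrisprArray]] = {}
    primers: dict[str, crispr_typing.PrimerCandidate | None] = {}
    if config.run_crispr:
        t = stage("crispr")
        for rec in records:
            found = crispr_typing.detect_arrays_in_record(rec)
            if found:
                arrays[rec.strain_id] = found
        _write_arrays_tsv(arrays, out / "arrays.tsv")
        manifest["stages"]["crispr"] = {
            "n_strains_with_arrays": len(arrays),
            "n_arrays": sum(len(v) for v in arrays.values()),
            "seconds": round(time.time() - t, 2),
        }
        if config.run_primers:
            t = stage("primers")
            by_id = {r.strain_id: r for r in records}
            targets = sorted(arrays)[: config.n_primer_targets]
            for sid in targets:
                primers[sid] = crispr_typing.design_strain_primers(
                    arrays[sid][0], by_id[sid], records
                )
            _write_primers_tsv(primers, out / "primers.tsv")
            manifest["stages"]["primers"] = {
                "n_targets": len(targets),
                "n_accepted": sum(p is not None for p in primers.values()),
                "seconds": round(time.time() - t, 2),
            }

    # --- transmission -----------------------------------------------------
    t = stage("transmission")
    calls = transmission.call_transmissions(
        records, matrix, arrays, ani_threshold=config.ani_threshold
    )
    _write_calls_tsv(calls, out / "transmission.tsv")
    manifest["stages"]["transmission"] = {
        "n_pairs": len(calls),
        "n_transmitted": sum(c.verdict == "transmitted" for c in calls),
        "seconds": round(time.time() - t, 2),
    }

    # --- phylogeny --------------------------------------------------------
    tree = None
    if config.run_phylo:
        t = stage("phylogeny")
        tree = _core_tree(config, records, families, sc_core)
        (out / "core_tree.nwk").write_text(tree.to_newick() + "\n")
        manifest["stages"]["phylogeny"] = {
            "n_families_used": min(config.n_phylo_families, len(sc_core)),
            "bootstrap_reps": config.bootstrap_reps,
            "seconds": round(time.time() - t, 2),
        }

    # --- manifest ---------------------------------------------------------
    manifest["config"] = _config_dict(config)
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.nwk"))
    }
    manifest["total_seconds"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return PipelineResult(
        out_dir=out,
        records=records,
        ledger=ledger,
        families=families,
        matrix=matrix,
        single_copy_core=sc_core,
        enrichment=enr,
        orf_age=orf_age,
        arrays=arrays,
        primers=primers,
        calls=calls,
        tree=tree,
        manifest=manifest,
    )


def default_outgroup(records: list[StrainRecord]) -> str:
    """Designated outgroup: first strain not assigned to any family."""
    for r in sorted(records, key=lambda r: r.strain_id):
        if not r.family_id:
            return r.strain_id
    return sorted(r.strain_id for r in records)[0]


def _core_tree(
    config: PipelineConfig,
    records: list[StrainRecord],
    families: list[orthology.GeneFamily],
    sc_core: list[str],
) -> core_phylogeny.Tree:
    chosen = sc_core[: config.n_phylo_families]
    if not chosen:
        raise RuntimeError("no single-copy core families available for phylogeny")
    cds_of = {r.strain_id: dict(r.cds) for r in records}
    fam_by_id = {f.gf_id: f for f in families}
    alignments = []
    for gf in chosen:
        fam = fam_by_id[gf]
        seqs = []
        for strain in sorted(fam.members):
            gene_id = fam.members[strain][0]
            seqs.append((strain, cds_of[strain][gene_id]))
        alignments.append(core_phylogeny.align_family(seqs, source=gf))
    concat = core_phylogeny.concatenate(alignments)
    tree = core_phylogeny.bootstrap_consensus(
        concat, n_reps=config.bootstrap_reps, seed=_stage_seed(config.seed, 7)
    )
    outgroup = config.outgroup or default_outgroup(records)
    return core_phylogeny.root_on_outgroup(tree, outgroup)


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["out_dir"] = str(d["out_dir"])
    if d["cohort"] is not None:
        d["cohort"] = {
            k: v for k, v in d["cohort"].items() if k != "segmentation"
        }
        d["cohort"]["family_plan"] = [
            {
                "family_id": e["family_id"],
                "member_ages": list(e["member_ages"]),
                "transmitted_clone_flags": list(e["transmitted_clone_flags"]),
            }
            for e in d["cohort"]["family_plan"]
        ]
    return json.loads(json.dumps(d, default=str))


def _write_arrays_tsv(arrays, path: Path) -> None:
    # one row per spacer, 1-based inclusive coordinates
    with open(path, "w", newline="\n") as fh:
        fh.write("strain_id\tcontig_id\tarray_start\tarray_end\tspacer_index\tspacer\n")
        for sid in sorted(arrays):
            for arr in arrays[sid]:
                for i, sp in enumerate(arr.spacers, start=1):
                    fh.write(
                        f"{sid}\t{arr.contig_id}\t{arr.start + 1}\t{arr.end}\t{i}\t{sp}\n"
                    )


def _write_primers_tsv(primers, path: Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(
            "strain_id\tforward\treverse\tamplicon_length\taccepted\n"
        )
        for sid in sorted(primers):
            p = primers[sid]
            if p is None:
                fh.write(f"{sid}\t\t\t\tno\n")
            else:
                fh.write(
                    f"{sid}\t{p.forward}\t{p.reverse}\t{p.amplicon_length}\tyes\n"
                )


def _write_calls_tsv(calls, path: Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(
            "strain_a\tstrain_b\tfamily_id\tani\tgene_jaccard\tspacer_class\tverdict\n"
        )
        for c in calls:
            fh.write(
                f"{c.strain_a}\t{c.strain_b}\t{c.family_id}\t{c.ani:.4f}"
                f"\t{c.gene_jaccard:.4f}\t{c.spacer_class}\t{c.verdict}\n"
            )


# ---------------------------------------------------------------------------
# Truth evaluation
# ---------------------------------------------------------------------------

def evaluate_against_truth(result: PipelineResult) -> dict[str, float]:
    """Score every planted signal of the run against its truth ledger."""
    ledger = result.ledger
    metrics: dict[str, float] = {}

    # gene-family recovery: planted gene sets recovered exactly
    inferred = {f.gene_ids() for f in result.families}
    truth_sets = [frozenset(f.gene_ids) for f in ledger.families.values()]
    exact = sum(1 for s in truth_sets if s in inferred)
    metrics["gf_recovery_pct"] = 100.0 * exact / len(truth_sets)
    metrics["n_true_families"] = float(len(truth_sets))
    metrics["n_inferred_families"] = float(len(result.families))

    # single-copy core recovery (ids differ between truth and inference;
    # compare via gene sets)
    truth_scc = {
        frozenset(ledger.families[gf].gene_ids) for gf in ledger.single_copy_core
    }
    inferred_scc = {
        next(f.gene_ids() for f in result.families if f.gf_id == gf)
        for gf in result.single_copy_core
    }
    metrics["single_copy_core_exact"] = float(truth_scc == inferred_scc)
    metrics["n_single_copy_core"] = float(len(result.single_copy_core))

    # enrichment direction recovery
    gf_of_gene = {}
    for f in result.families:
        for g in f.gene_ids():
            gf_of_gene[g] = f.gf_id
    direction_of: dict[str, str] = {r.gf_id: r.direction for r in result.enrichment}
    planted = [
        f for f in ledger.families.values() if f.direction in ("younger", "older")
    ]
    correct = 0
    opposite = 0
    for f in planted:
        any_gene = next(iter(f.gene_ids))
        called = direction_of.get(gf_of_gene.get(any_gene, ""), "none")
        if called == f.direction:
            correct += 1
        elif called != "none":
            opposite += 1
    metrics["enrichment_sensitivity"] = correct / len(planted) if planted else 1.0
    metrics["enrichment_false_direction"] = (
        opposite / len(planted) if planted else 0.0
    )
    neutral = [f for f in ledger.families.values() if f.kind == "dispensable" and f.direction == "none"]
    n_neutral_called = 0
    for f in neutral:
        any_gene = next(iter(f.gene_ids))
        if direction_of.get(gf_of_gene.get(any_gene, ""), "none") != "none":
            n_neutral_called += 1
    metrics["neutral_call_rate"] = (
        n_neutral_called / len(neutral) if neutral else 0.0
    )

    # CRISPR recovery
    planted_arrays = ledger.arrays
    recall_hits = 0
    spacer_exact = 0
    for sid, truth_arr in planted_arrays.items():
        found = result.arrays.get(sid, [])
        match = [
            a
            for a in found
            if a.contig_id == truth_arr.contig_id
            and a.start == truth_arr.start
            and a.end == truth_arr.end
        ]
        if match:
            recall_hits += 1
            if match[0].spacers == truth_arr.spacers:
                spacer_exact += 1
    n_planted = len(planted_arrays)
    metrics["crispr_recall"] = recall_hits / n_planted if n_planted else 1.0
    metrics["crispr_spacer_exact"] = (
        spacer_exact / n_planted if n_planted else 1.0
    )
    extra = sum(
        len(result.arrays.get(sid, [])) - (1 if sid in planted_arrays else 0)
        for sid in set(result.arrays) | set(planted_arrays)
    )
    metrics["crispr_false_arrays"] = float(extra)
    metrics["crispr_positive_strains"] = float(len(result.arrays))

    # transmission
    truth_pairs = {frozenset((a, b)) for a, b, _ in ledger.transmitted_pairs}
    called_pairs = {
        frozenset((c.strain_a, c.strain_b))
        for c in result.calls
        if c.verdict == "transmitted"
    }
    tp = len(truth_pairs & called_pairs)
    metrics["transmission_precision"] = (
        tp / len(called_pairs) if called_pairs else 1.0
    )
    metrics["transmission_recall"] = tp / len(truth_pairs) if truth_pairs else 1.0
    comps = transmission.transmitted_components(result.calls)
    metrics["n_transmission_components"] = float(len(comps))
    metrics["largest_transmission_component"] = float(
        max((len(c) for c in comps), default=0)
    )

    # clone-clade support on the rooted consensus tree
    if result.tree is not None and ledger.transmitted_pairs:
        chains: dict[str, set[str]] = {}
        for a, b, fam in ledger.transmitted_pairs:
            chains.setdefault(fam, set()).update((a, b))
        largest = max(chains.values(), key=len)
        sup = result.tree.support_of_clade(largest)
        metrics["clone_clade_support"] = float(sup) if sup is not None else 0.0

    metrics["orf_age_rho"] = result.orf_age.rho
    metrics["orf_age_p"] = result.orf_age.p_value
    return metrics
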