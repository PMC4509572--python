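"""Pipeline orchestration: run every evaluation stage and emit a report bundle.

The bundle mirrors the tables a barcode-evaluation study reports:
sequence recovery, supported-monophyly resolution per locus combination
and rank, leave-one-out and cross-plot identification success,
shared-taxa counts between plots, the misidentification audit,
clade-richness ratios and the intraspecific-variation tally.  Every
stage is emitted even when empty, with explicit markers, and a manifest
records the configuration, seed and package version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field, asdict, is_dataclass
from itertools import combinations as iter_combinations
from pathlib import Path
from typing import Any, Mapping, Sequence

from ._util import ratio
from .assignment import evaluate_cross_plot, evaluate_leave_one_out, EvalReport
from .audit import audit_summary, flag_conflicts
from .datamodel import Dataset, LocusAlignment, ValidationError, recovery_stats
from .io import write_dataset, write_json, write_tsv
from .resolution import monophyly_status, resolution_rates
from .simulate import SimConfig, generate_dataset
from .supermatrix import Supermatrix, concatenate, concatenate_family_blocks
from .trees import DISTANCE_MODELS, SupportTree, bootstrap_support, neighbor_joining


@dataclass
class PipelineConfig:
    """Declarative configuration for a full run."""

    sim: SimConfig | None = None  # synthetic mode when set
    meta_path: str | None = None  # file mode otherwise
    locus_paths: Mapping[str, Any] | None = None
    tree_combinations: Sequence[Sequence[str]] | None = None  # default from loci
    blast_combinations: Sequence[Sequence[str]] | None = None
    bootstrap_replicates: int = 1000
    support_cutoff: float = 50.0
    identity_threshold: float = 0.95
    distance_model: str = "k2p"
    db_plot: str = "BB"
    core_loci: tuple[str, ...] = ("rbcL", "matK")
    audit_min_support: float = 50.0
    seed: int = 0
    outdir: str = "barcodeval_out"

    def __post_init__(self) -> None:
        if self.sim is None and (self.meta_path is None or self.locus_paths is None):
            raise ValidationError("either sim config or input paths required")
        if not 0 < self.identity_threshold <= 1:
            raise ValidationError("identity_threshold outside (0,1]")
        if not 0 <= self.support_cutoff <= 100:
            raise ValidationError("support_cutoff outside [0,100]")
        if self.distance_model not in DISTANCE_MODELS:
            raise ValidationError(f"unknown distance model {self.distance_model!r}")


def clade_richness_ratios(n_individuals: int, n_genera: int, n_species: int) -> dict:
    """Individuals/genus and species/genus ratios, reporting precision included."""
    return {
        "individuals": n_individuals,
        "genera": n_genera,
        "species": n_species,
        "I_G": ratio(n_individuals, n_genera, 1),
        "S_G_1dp": ratio(n_species, n_genera, 1),
        "S_G_2dp": ratio(n_species, n_genera, 2),
    }


def shared_taxa_counts(
    dataset: Dataset, plot_pairs: Sequence[tuple[str, str]], loci: Sequence[str]
) -> list[dict]:
    """Species and genera with >=1 sequenced individual in both plots, per locus."""
    by_id = dataset.by_id
    plots = {s.plot for s in dataset.specimens}
    out = []
    for a, b in plot_pairs:
        for p in (a, b):
            if p not in plots:
                raise ValidationError(f"unknown plot label {p!r}")
        for locus in loci:
            members = dataset.members(locus)
            sp_a = {by_id[m].species for m in members if by_id[m].plot == a}
            sp_b = {by_id[m].species for m in members if by_id[m].plot == b}
            gn_a = {by_id[m].genus for m in members if by_id[m].plot == a}
            gn_b = {by_id[m].genus for m in members if by_id[m].plot == b}
            out.append(
                {
                    "plot_a": a,
                    "plot_b": b,
                    "locus": locus,
                    "shared_species": len(sp_a & sp_b),
                    "shared_genera": len(gn_a & gn_b),
                }
            )
    return out


def build_supermatrix(dataset: Dataset, loci: Sequence[str]) -> Supermatrix:
    """Concatenate the given loci (union members), block loci included."""
    parts: dict[str, LocusAlignment] = {}
    for locus in loci:
        aln = dataset.alignments[locus]
        if isinstance(aln, LocusAlignment):
            parts[locus] = aln
        else:
            parts[locus] = concatenate_family_blocks(aln, dataset.specimens)
    return concatenate(parts, member_policy="union")


def tree_for_combination(
    dataset: Dataset,
    loci: Sequence[str],
    replicates: int,
    seed: int,
    model: str = "k2p",
) -> tuple[SupportTree, list[str]]:
    """Supermatrix -> NJ -> bootstrap for one locus combination.

    Members with undefined pairwise distances (no shared scored sites
    with someone, possible with block loci) are removed greedily, most
    conflicted first; the removed ids are returned for logging.
    """
    sm = build_supermatrix(dataset, loci)
    aln = sm.as_alignment("+".join(loci))
    dist_fn = DISTANCE_MODELS[model]
    removed: list[str] = []
    D = dist_fn(aln)
    while True:
        undef = D.undefined_pairs()
        if not undef:
            break
        counts: dict[str, int] = {}
        for a, b in undef:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        worst = sorted(counts, key=lambda m: (-counts[m], m))[0]
        removed.append(worst)
        keep = [m for m in aln.members if m != worst]
        if len(keep) < 3:
            raise ValidationError(
                f"{'+'.join(loci)}: fewer than 3 members left after removing "
                "undefined pairs"
            )
        aln = aln.subset(keep)
        D = dist_fn(aln)
    base = neighbor_joining(D)
    boot = bootstrap_support(
        aln, base, replicates, seed, partitions=sm.partition_ranges(), model=model
    )
    return boot.tree, removed


def _default_tree_combinations(dataset: Dataset, core: Sequence[str]) -> list[list[str]]:
    """Single global loci, the core pair, and core plus each supplement."""
    global_loci = [
        l for l in dataset.loci if isinstance(dataset.alignments[l], LocusAlignment)
    ]
    block_loci = [l for l in dataset.loci if l not in global_loci]
    combos: list[list[str]] = [[l] for l in global_loci]
    core = [l for l in core if l in dataset.loci]
    if len(core) >= 2:
        combos.append(list(core))
        for extra in [l for l in dataset.loci if l not in core]:
            combos.append(list(core) + [extra])
        rest = [l for l in dataset.loci if l not in core]
        if len(rest) >= 2:
            combos.append(list(core) + rest)
    # a block-diagonal locus alone carries no cross-family signal; it is
    # only evaluated inside combinations with a global locus
    return [c for c in combos if any(l not in block_loci for l in c)]


def _default_blast_combinations(dataset: Dataset, core: Sequence[str]) -> list[list[str]]:
    combos: list[list[str]] = [[l] for l in dataset.loci]
    core = [l for l in core if l in dataset.loci]
    if len(core) >= 2:
        combos.append(list(core))
        for extra in [l for l in dataset.loci if l not in core]:
            combos.append(list(core) + [extra])
        rest = [l for l in dataset.loci if l not in core]
        if len(rest) >= 2:
            combos.append(list(core) + rest)
    return combos


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class PipelineResult:
    outdir: Path
    dataset: Dataset
    recovery: Any
    resolution: list[Any] = dc_field(default_factory=list)
    loo_reports: list[EvalReport] = dc_field(default_factory=list)
    cross_reports: list[EvalReport] = dc_field(default_factory=list)
    audit: Any = None
    flags: list[Any] = dc_field(default_factory=list)
    ratios: dict = dc_field(default_factory=dict)
    shared: list[dict] = dc_field(default_factory=list)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        if config.sim is not None:
            dataset, truth = generate_dataset(config.sim)
            write_dataset(dataset, outdir / "inputs")
            write_tsv(
                outdir / "inputs" / "ground_truth.tsv",
                ["sample_id", "true_species", "true_genus", "true_family",
                 "recorded_species", "recorded_genus", "recorded_family", "level"],
                [
                    [e.sample_id, e.true_species, e.true_genus, e.true_family,
                     e.recorded_species, e.recorded_genus, e.recorded_family, e.level]
                    for e in truth.errors
                ],
            )
        else:
            from .io import read_dataset

            dataset = read_dataset(config.meta_path, config.locus_paths)

        stage = "recovery"
        rec = recovery_stats(dataset)
        write_json(
            outdir / "recovery.json",
            {
                "n_specimens": rec.n_specimens,
                "per_locus_count": rec.per_locus_count,
                "per_locus_percent": rec.per_locus_percent,
                "any_marker_count": rec.any_marker_count,
                "any_marker_percent": rec.any_marker_percent,
            },
        )

        stage = "ratios"
        n_sp = len({s.species for s in dataset.specimens})
        n_gn = len({s.genus for s in dataset.specimens})
        ratios = clade_richness_ratios(len(dataset.specimens), n_gn, n_sp)
        write_json(outdir / "ratios.json", ratios)

        stage = "resolution"
        tree_combos = config.tree_combinations or _default_tree_combinations(
            dataset, config.core_loci
        )
        by_id = dataset.by_id
        res_rows = []
        resolution_reports = []
        trees_cache: dict[str, SupportTree] = {}
        for combo in tree_combos:
            label = "+".join(combo)
            tree, removed = tree_for_combination(
                dataset,
                combo,
                config.bootstrap_replicates,
                seed=config.seed,
                model=config.distance_model,
            )
            trees_cache[label] = tree
            (outdir / "trees").mkdir(exist_ok=True)
            (outdir / "trees" / f"{label.replace('/', '_')}.nwk").write_text(
                tree.newick() + "\n"
            )
            for rank, attr in (
                ("species", "species"), ("genus", "genus"), ("family", "family")
            ):
                labels = {m: getattr(by_id[m], attr) for m in tree.leaves}
                statuses = monophyly_status(tree, labels, rank, config.support_cutoff)
                try:
                    rep = resolution_rates(statuses, rank, label)
                    res_rows.append([label, rank, rep.eligible, rep.supported, rep.rate])
                    resolution_reports.append(rep)
                except ValidationError:
                    res_rows.append([label, rank, 0, 0, "NA"])
            if removed:
                res_rows.append([label, "removed_members", len(removed), "", ";".join(removed)])
        write_tsv(
            outdir / "resolution.tsv",
            ["combination", "rank", "eligible", "supported", "rate"],
            res_rows,
        )

        stage = "assignment_loo"
        blast_combos = config.blast_combinations or _default_blast_combinations(
            dataset, config.core_loci
        )
        loo_reports = []
        loo_rows = []
        for combo in blast_combos:
            rep = evaluate_leave_one_out(dataset, combo, config.identity_threshold)
            loo_reports.append(rep)
            loo_rows.append(
                [
                    rep.label,
                    rep.species_denominator,
                    rep.species_rate if rep.species_rate is not None else "NA",
                    rep.genus_denominator,
                    rep.genus_rate if rep.genus_rate is not None else "NA",
                    rep.species_outcomes["no_assignment"],
                    rep.species_outcomes["unscorable"],
                ]
            )
        write_tsv(
            outdir / "assignment_loo.tsv",
            ["combination", "species_n", "species_rate", "genus_n", "genus_rate",
             "no_assignment", "unscorable"],
            loo_rows,
        )

        stage = "assignment_cross_plot"
        plots = sorted({s.plot for s in dataset.specimens})
        cross_reports = []
        cross_rows = []
        if config.db_plot in plots and len(plots) > 1:
            for combo in blast_combos:
                reports = evaluate_cross_plot(
                    dataset, config.db_plot, plots, combo, config.identity_threshold
                )
                cross_reports.extend(reports)
                for rep in reports:
                    cross_rows.append(
                        [
                            rep.label, rep.db_plot, rep.query_plot,
                            rep.n_shared_species, rep.n_shared_genera,
                            rep.species_denominator,
                            rep.species_rate if rep.species_rate is not None else "NA",
                            rep.genus_denominator,
                            rep.genus_rate if rep.genus_rate is not None else "NA",
                        ]
                    )
        write_tsv(
            outdir / "assignment_crossplot.tsv",
            ["combination", "db_plot", "query_plot", "shared_species", "shared_genera",
             "species_n", "species_rate", "genus_n", "genus_rate"],
            cross_rows,
        )

        stage = "shared_taxa"
        pairs = list(iter_combinations(plots, 2))
        shared = shared_taxa_counts(dataset, pairs, dataset.loci) if pairs else []
        write_tsv(
            outdir / "shared_taxa.tsv",
            ["plot_a", "plot_b", "locus", "shared_species", "shared_genera"],
            [[d["plot_a"], d["plot_b"], d["locus"], d["shared_species"], d["shared_genera"]]
             for d in shared],
        )

        stage = "audit"
        core = [l for l in config.core_loci if l in dataset.loci]
        flags = []
        summary = None
        core_label = "+".join(core)
        if core and core_label in trees_cache:
            tree = trees_cache[core_label]
        elif core:
            tree, _ = tree_for_combination(
                dataset, core, config.bootstrap_replicates,
                seed=config.seed, model=config.distance_model,
            )
        else:
            tree = None
        if tree is not None:
            flags = flag_conflicts(tree, by_id, config.audit_min_support)
            summary = audit_summary(flags, n_audited=len(tree.leaves))
        write_tsv(
            outdir / "audit_flags.tsv",
            ["sample_id", "recorded_species", "recorded_genus", "recorded_family",
             "neighborhood_species", "neighborhood_genus", "neighborhood_family",
             "level", "support"],
            [
                [f.sample_id, f.recorded_species, f.recorded_genus, f.recorded_family,
                 f.neighborhood_species, f.neighborhood_genus, f.neighborhood_family,
                 f.level, f.support if f.support is not None else "NA"]
                for f in flags
            ],
        )
        write_json(
            outdir / "audit_summary.json",
            {
                "n_audited": summary.n_audited if summary else 0,
                "n_flagged": summary.n_flagged if summary else 0,
                "flag_rate": summary.flag_rate if summary else "NA",
                "level_counts": summary.level_counts if summary else {},
                "level_shares": summary.level_shares if summary else {},
            },
        )

        stage = "intraspecific_variation"
        from .trees import intraspecific_variation

        var_rows = []
        for locus in dataset.loci:
            for v in intraspecific_variation(dataset, locus):
                var_rows.append(
                    [locus, v.species, v.n_members, v.n_variable_sites,
                     v.n_within_plot, v.n_between_plot_only, ";".join(v.plots)]
                )
        write_tsv(
            outdir / "intraspecific_variation.tsv",
            ["locus", "species", "n_members", "variable_sites",
             "within_plot", "between_plot_only", "plots"],
            var_rows,
        )

        stage = "manifest"
        cfg_payload = _jsonable(config)
        cfg_payload.pop("outdir", None)  # output location is not part of the run
        cfg_json = json.dumps(cfg_payload, sort_keys=True)
        from . import __version__

        write_json(
            outdir / "manifest.json",
            {
                "config": json.loads(cfg_json),
                "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
                "seed": config.seed,
                "barcodeval_version": __version__,
            },
        )
    except ValidationError as exc:
        raise ValidationError(f"stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        outdir=outdir,
        dataset=dataset,
        recovery=rec,
        resolution=resolution_reports,
        loo_reports=loo_reports,
        cross_reports=cross_reports,
        audit=summary,
        flags=flags,
        ratios=ratios,
        shared=shared,
    )
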