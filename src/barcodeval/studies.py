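"""Self-contained evaluation studies on synthetic data.

These functions define the reference experiments the package is judged
against: parameter recovery under a clean barcode gap (supported
monophyly and leave-one-out identification should be perfect, injected
errors should be flagged), and the directional effects the method
predicts — higher clade richness (species/genus ratio) depressing
species-level identification, between-plot intraspecific divergence
depressing cross-plot identification, and locus combinations beating
their constituent single loci.

Problem sizes are deliberately desk-scale (tens of specimens, 20
replicate seeds, 100 bootstrap replicates) so a full run completes in
minutes on one CPU; the qualitative contrasts they probe do not depend
on the census size.
"""

from __future__ import annotations

from dataclasses import replace
from statistics import mean

import numpy as np

from ._util import percent, ratio
from .assignment import evaluate_cross_plot, evaluate_leave_one_out
from .audit import flag_conflicts
from .datamodel import recovery_stats
from .pipeline import tree_for_combination
from .resolution import monophyly_status, resolution_rates
from .simulate import LocusConfig, SimConfig, generate_dataset

N_SEEDS = 20
BOOTSTRAP_REPLICATES = 100


def _spawn_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def printed_arithmetic() -> dict[str, float]:
    """The study's self-contained report arithmetic, recomputed.

    Counts are inputs (census sizes, flag counts, shared-table rows);
    the reported quantities are the half-up-rounded percentages and
    clade-richness ratios the package prints for them.
    """
    return {
        "any_marker_recovery_percent": percent(1858, 2052),
        "misidentification_rate_percent": percent(99, 1033),
        "family_error_share_percent": percent(74, 96),
        "genus_error_share_percent": percent(17, 96),
        "species_error_share_percent": percent(5, 96),
        "individuals_per_genus_local": ratio(2052, 259),
        "species_per_genus_local": ratio(655, 259),
        "individuals_per_genus_amazon": ratio(1073, 143),
        "individuals_per_genus_panama": ratio(1035, 181),
    }


def _gap_config(seed: int, **overrides) -> SimConfig:
    base = dict(
        n_families=3,
        genera_per_family=2,
        species_per_genus=2,
        samples_per_species=(2, 3),
        loci=(
            LocusConfig("rbcL", 1000, inter_species_height=0.05,
                        intra_species_height=0.001),
            LocusConfig("matK", 1000, inter_species_height=0.05,
                        intra_species_height=0.001),
        ),
        misid_rate=0.0,
        between_plot_extra=0.0,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def parameter_recovery(master_seed: int, n_seeds: int = N_SEEDS) -> dict[str, float]:
    """Clean-gap recovery: resolution, identification, audit recall.

    With intraspecific height 0.001 far below interspecific height 0.05
    and 1000-column loci, supported-monophyly species resolution and
    leave-one-out species identification should both be 100%, no clean
    specimen should be flagged, and >=95% of injected family/genus
    misidentifications should be recovered.
    """
    seeds = _spawn_seeds(master_seed, n_seeds)
    resolution = []
    loo_species = []
    false_flags = 0
    recall_hits = recall_total = 0
    for seed in seeds:
        # clean dataset: perfect resolution, perfect LOO, zero flags
        ds, _ = generate_dataset(_gap_config(seed))
        tree, _ = tree_for_combination(
            ds, ["rbcL", "matK"], BOOTSTRAP_REPLICATES, seed=seed
        )
        by_id = ds.by_id
        labels = {m: by_id[m].species for m in tree.leaves}
        rep = resolution_rates(
            monophyly_status(tree, labels, "species"), "species", "R+M"
        )
        resolution.append(rep.rate)
        loo = evaluate_leave_one_out(ds, ["rbcL", "matK"])
        loo_species.append(loo.species_rate)
        false_flags += len(flag_conflicts(tree, by_id))

        # corrupted twin: injected errors must be recovered
        ds_err, truth = generate_dataset(_gap_config(seed, misid_rate=0.1))
        tree_err, _ = tree_for_combination(
            ds_err, ["rbcL", "matK"], BOOTSTRAP_REPLICATES, seed=seed
        )
        flagged = {f.sample_id for f in flag_conflicts(tree_err, ds_err.by_id)}
        injected = {
            e.sample_id for e in truth.errors if e.level in ("family", "genus")
        }
        recall_hits += len(flagged & injected)
        recall_total += len(injected)
    return {
        "species_resolution_percent": mean(resolution),
        "species_resolution_min": min(resolution),
        "loo_species_percent": mean(loo_species),
        "loo_species_min": min(loo_species),
        "clean_false_flags": false_flags,
        "audit_recall_percent": percent(recall_hits, recall_total),
        "n_seeds": n_seeds,
    }


def _richness_config(seed: int, genera: int, species_range, **overrides) -> SimConfig:
    # moderate divergence and shorter loci so identification is fallible
    # and the clade-richness contrast has room to show
    base = dict(
        n_families=1,
        genera_per_family=genera,
        species_per_genus=species_range,
        samples_per_species=2,
        loci=(
            LocusConfig("rbcL", 300, inter_species_height=0.02,
                        intra_species_height=0.003),
        ),
        misid_rate=0.0,
        between_plot_extra=0.0,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def clade_richness_effect(master_seed: int, n_seeds: int = N_SEEDS) -> dict[str, float]:
    """Species/genus-ratio effect on leave-one-out species identification.

    Two regimes at identical divergence parameters and comparable
    species counts: high clade richness (about 2.5 species per genus)
    versus low (about 1.5); more congeners means more near-identical
    heterospecific neighbours, so the high-richness regime should
    identify a smaller share of specimens to species.
    """
    seeds = _spawn_seeds(master_seed + 1, n_seeds)
    rates: dict[str, list[float]] = {"high": [], "low": []}
    for seed in seeds:
        for label, genera, spread in (("high", 8, (2, 3)), ("low", 13, (1, 2))):
            ds, _ = generate_dataset(_richness_config(seed, genera, spread))
            rep = evaluate_leave_one_out(ds, ["rbcL"])
            if rep.species_rate is not None:
                rates[label].append(rep.species_rate)
    return {
        "high_richness_species_percent": mean(rates["high"]),
        "low_richness_species_percent": mean(rates["low"]),
        "n_seeds": n_seeds,
    }


def cross_plot_effect(master_seed: int, n_seeds: int = N_SEEDS) -> dict[str, float]:
    """Within-plot vs cross-plot identification with plot-structured divergence.

    Conspecifics from different plots carry extra divergence; queries
    from another plot should therefore be identified at a rate no better
    than queries from the database plot itself.
    """
    seeds = _spawn_seeds(master_seed + 2, n_seeds)
    within, cross = [], []
    for seed in seeds:
        cfg = _richness_config(
            seed, 6, (1, 2),
            samples_per_species=4,
            plots=(("BB", 1.0), ("JJYL", 1.0)),
            loci=(
                LocusConfig("rbcL", 300, inter_species_height=0.02,
                            intra_species_height=0.001),
            ),
            between_plot_extra=0.002,
        )
        ds, _ = generate_dataset(cfg)
        reports = evaluate_cross_plot(ds, "BB", ["BB", "JJYL"], ["rbcL"])
        by_plot = {r.query_plot: r for r in reports}
        w, c = by_plot["BB"].species_rate, by_plot["JJYL"].species_rate
        if w is not None and c is not None:
            within.append(w)
            cross.append(c)
    return {
        "within_plot_species_percent": mean(within),
        "cross_plot_species_percent": mean(cross),
        "n_seeds": n_seeds,
    }


def combination_effect(master_seed: int, n_seeds: int = N_SEEDS) -> dict[str, float]:
    """Locus combinations vs their constituent single loci (leave-one-out).

    Two loci with the same divergence structure but independent
    substitution noise: pooling scored sites averages the noise away, so
    the combination should identify at least as well as either locus.
    """
    seeds = _spawn_seeds(master_seed + 3, n_seeds)
    single_a, single_b, combo = [], [], []
    for seed in seeds:
        cfg = _richness_config(seed, 8, (2, 3))
        cfg = replace(
            cfg,
            loci=(
                LocusConfig("rbcL", 300, inter_species_height=0.02,
                            intra_species_height=0.003),
                LocusConfig("matK", 300, inter_species_height=0.02,
                            intra_species_height=0.003),
            ),
        )
        ds, _ = generate_dataset(cfg)
        ra = evaluate_leave_one_out(ds, ["rbcL"]).species_rate
        rb = evaluate_leave_one_out(ds, ["matK"]).species_rate
        rc = evaluate_leave_one_out(ds, ["rbcL", "matK"]).species_rate
        if None not in (ra, rb, rc):
            single_a.append(ra)
            single_b.append(rb)
            combo.append(rc)
    return {
        "single_rbcL_species_percent": mean(single_a),
        "single_matK_species_percent": mean(single_b),
        "combined_species_percent": mean(combo),
        "n_seeds": n_seeds,
    }


def recovery_headline(master_seed: int) -> dict[str, float]:
    """Recovery statistics of one default-profile synthetic campaign."""
    cfg = SimConfig(seed=_spawn_seeds(master_seed + 4, 1)[0])
    ds, _ = generate_dataset(cfg)
    stats = recovery_stats(ds)
    return {
        "n_specimens": stats.n_specimens,
        "any_marker_percent": stats.any_marker_percent,
        **{f"{locus}_percent": p for locus, p in stats.per_locus_percent.items()},
    }
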