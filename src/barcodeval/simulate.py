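"""Synthetic barcode datasets with the structure the evaluation assumes.

The generator emulates a plot-based tropical-tree barcoding campaign:
a nested taxonomy (families > genera > species, 1-6 specimens per
species), per-locus aligned sequences whose intraspecific divergence is
far smaller than interspecific divergence (the barcode gap), per-locus
Bernoulli sequence-recovery failure, multi-plot specimen allocation with
optional extra between-plot intraspecific divergence, and injectable
field-misidentification errors at the family, genus or species level.

Sequences evolve under Jukes-Cantor (single substitution rate, no
indels) along a taxonomy-concordant ultrametric tree: lineages coalesce
within disjoint depth bands per rank (conspecifics shallowest, then
congeners, then confamilials), so each named taxon is a clade of the
true tree.  Within a species the genealogy is a star, optionally with a
per-plot substructure so conspecifics from different plots are more
divergent than plot-mates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .datamodel import Dataset, LocusAlignment, SpecimenRecord, ValidationError

_BASES = np.array(list("ACGT"))

# fraction of the interspecific root height at which each rank's
# coalescences may occur (times before present, tips at 0)
_SPECIES_BAND = (0.20, 0.45)
_GENUS_BAND = (0.50, 0.75)
_FAMILY_BAND = (0.80, 1.00)


@dataclass(frozen=True)
class LocusConfig:
    """Parameters for one simulated barcode locus.

    Heights are in expected substitutions per site from tip to node:
    ``inter_species_height`` is the root height of the (ultrametric)
    species tree, ``intra_species_height`` the depth at which
    conspecific lineages attach, so the expected conspecific pairwise
    divergence is about twice the intra height.
    """

    name: str
    length: int = 700
    inter_species_height: float = 0.05
    intra_species_height: float = 0.001
    recovery_rate: float = 1.0
    family_blocks: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValidationError(f"{self.name}: length must be >= 1")
        if not 0.0 <= self.recovery_rate <= 1.0:
            raise ValidationError(f"{self.name}: recovery_rate outside [0,1]")


@dataclass(frozen=True)
class SimConfig:
    """Full study design for one synthetic dataset.

    Counts may be a fixed int or an inclusive (lo, hi) range sampled per
    parent taxon.  Defaults mirror a four-plot tropical-tree inventory:
    plots weighted like a large permanent plot plus three smaller ones,
    1-6 specimens per species, four loci with recovery rates matching a
    realistic mixed success profile, and a ~9.6% field-misidentification
    rate split 74:17:5 across family/genus/species levels.
    """

    n_families: int | tuple[int, int] = 5
    genera_per_family: int | tuple[int, int] = (1, 4)
    species_per_genus: int | tuple[int, int] = (1, 4)
    samples_per_species: int | tuple[int, int] = (1, 6)
    loci: tuple[LocusConfig, ...] = (
        LocusConfig("rbcL", length=700, recovery_rate=0.806),
        LocusConfig("matK", length=800, recovery_rate=0.693),
        LocusConfig("trnH-psbA", length=500, recovery_rate=0.697, family_blocks=True),
        LocusConfig("ITS", length=700, recovery_rate=0.525),
    )
    plots: tuple[tuple[str, float], ...] = (
        ("BB", 1019.0),
        ("JJYL", 725.0),
        ("GGYL", 220.0),
        ("LSL", 88.0),
    )
    misid_rate: float = 0.096
    misid_level_mix: tuple[float, float, float] = (74.0, 17.0, 5.0)
    between_plot_extra: float = 0.0005
    allow_inverted_gap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.misid_rate <= 1.0:
            raise ValidationError("misid_rate outside [0,1]")
        if self.between_plot_extra < 0:
            raise ValidationError("between_plot_extra must be >= 0")
        for lc in self.loci:
            total_intra = lc.intra_species_height + self.between_plot_extra
            if total_intra >= lc.inter_species_height and not self.allow_inverted_gap:
                raise ValidationError(
                    f"{lc.name}: intraspecific height {total_intra} is not below "
                    f"interspecific height {lc.inter_species_height} — inverted "
                    "barcode gap; set allow_inverted_gap=True to force"
                )
            if (
                total_intra >= _SPECIES_BAND[0] * lc.inter_species_height
                and not self.allow_inverted_gap
            ):
                raise ValidationError(
                    f"{lc.name}: intraspecific height {total_intra} reaches into "
                    "the interspecific coalescence band; reduce intra or raise inter"
                )


@dataclass(frozen=True)
class InjectedError:
    sample_id: str
    level: str  # family | genus | species
    true_species: str
    true_genus: str
    true_family: str
    recorded_species: str
    recorded_genus: str
    recorded_family: str


@dataclass
class GroundTruth:
    """True vs recorded taxonomy, with the list of injected errors."""

    true_records: list[SpecimenRecord]
    recorded_records: list[SpecimenRecord]
    errors: list[InjectedError] = field(default_factory=list)

    @property
    def true_by_id(self) -> dict[str, SpecimenRecord]:
        return {r.sample_id: r for r in self.true_records}

    def errors_at(self, level: str) -> list[InjectedError]:
        return [e for e in self.errors if e.level == level]


def _draw_count(spec: int | tuple[int, int], rng: np.random.Generator) -> int:
    if isinstance(spec, int):
        return spec
    lo, hi = spec
    return int(rng.integers(lo, hi + 1))


def generate_taxonomy(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[SpecimenRecord]:
    """Draw a nested taxonomy and allocate specimens to plots.

    Deterministic given the config seed.  Species names are synthetic
    binomials whose first token is the genus name.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    nf = _draw_count(config.n_families, rng)
    if nf < 1:
        raise ValidationError("zero-size taxonomy")
    plot_labels = [p for p, _ in config.plots]
    weights = np.array([w for _, w in config.plots], dtype=float)
    weights = weights / weights.sum()
    records: list[SpecimenRecord] = []
    g_idx = s_idx = 0
    sample_idx = 1
    for fi in range(nf):
        family = f"Famila{fi + 1:02d}ceae"
        ng = _draw_count(config.genera_per_family, rng)
        for _ in range(max(ng, 1)):
            g_idx += 1
            genus = f"Genusium{g_idx:03d}"
            ns = _draw_count(config.species_per_genus, rng)
            for _ in range(max(ns, 1)):
                s_idx += 1
                species = f"{genus} specius{s_idx:04d}"
                nsamp = _draw_count(config.samples_per_species, rng)
                for _ in range(max(nsamp, 1)):
                    plot = plot_labels[int(rng.choice(len(plot_labels), p=weights))]
                    records.append(
                        SpecimenRecord(
                            sample_id=f"s{sample_idx:05d}",
                            species=species,
                            genus=genus,
                            family=family,
                            plot=plot,
                        )
                    )
                    sample_idx += 1
    return records


# ---------------------------------------------------------------------------
# ultrametric taxonomy-concordant tree


@dataclass
class _Node:
    age: float
    children: list["_Node"] = field(default_factory=list)
    label: str | None = None  # set on specimen tips


def _yule_join(
    nodes: list[_Node], band: tuple[float, float], height: float, rng: np.random.Generator
) -> _Node:
    """Join lineages pairwise at ages drawn uniformly in the band (sorted)."""
    if len(nodes) == 1:
        return nodes[0]
    ages = np.sort(rng.uniform(band[0] * height, band[1] * height, len(nodes) - 1))
    pool = list(nodes)
    for age in ages:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        b = pool.pop(j)
        a = pool.pop(i)
        pool.append(_Node(age=float(age), children=[a, b]))
    return pool[0]


def _species_subtree(
    specimens: Sequence[SpecimenRecord],
    intra: float,
    extra: float,
    rng: np.random.Generator,
) -> _Node:
    """Star genealogy of conspecifics, with per-plot subroots when extra > 0."""
    tips = [_Node(age=0.0, label=s.sample_id) for s in specimens]
    root_age = intra + extra
    if extra <= 0 or len(specimens) < 2:
        return _Node(age=root_age, children=tips) if len(tips) > 1 else tips[0]
    plots = sorted({s.plot for s in specimens})
    if len(plots) == 1:
        return _Node(age=root_age, children=tips)
    plot_nodes = []
    for plot in plots:
        members = [t for t, s in zip(tips, specimens) if s.plot == plot]
        if len(members) == 1:
            plot_nodes.append(members[0])
        else:
            plot_nodes.append(_Node(age=intra, children=members))
    return _Node(age=root_age, children=plot_nodes)


def build_locus_tree(
    specimens: Sequence[SpecimenRecord],
    locus: LocusConfig,
    between_plot_extra: float,
    rng: np.random.Generator,
) -> _Node:
    """Ultrametric specimen tree concordant with the (true) taxonomy."""
    height = locus.inter_species_height
    families: dict[str, dict[str, dict[str, list[SpecimenRecord]]]] = {}
    for s in specimens:
        families.setdefault(s.family, {}).setdefault(s.genus, {}).setdefault(
            s.species, []
        ).append(s)
    family_nodes: list[_Node] = []
    for family in sorted(families):
        genus_nodes: list[_Node] = []
        for genus in sorted(families[family]):
            species_nodes = [
                _species_subtree(
                    families[family][genus][sp],
                    locus.intra_species_height,
                    between_plot_extra,
                    rng,
                )
                for sp in sorted(families[family][genus])
            ]
            genus_nodes.append(_yule_join(species_nodes, _SPECIES_BAND, height, rng))
        family_nodes.append(_yule_join(genus_nodes, _GENUS_BAND, height, rng))
    return _yule_join(family_nodes, _FAMILY_BAND, height, rng)


def _jc69_evolve(parent: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """One JC69 step of duration t (expected substitutions/site) per site."""
    if t <= 0:
        return parent.copy()
    p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    child = parent.copy()
    hit = rng.random(parent.size) < p_change
    n_hit = int(hit.sum())
    if n_hit:
        # substitute uniformly among the three other bases
        child[hit] = (parent[hit] + rng.integers(1, 4, n_hit)) % 4
    return child


def _simulate_sequences(
    root: _Node, length: int, rng: np.random.Generator
) -> dict[str, str]:
    out: dict[str, str] = {}
    root_seq = rng.integers(0, 4, length)
    stack: list[tuple[_Node, np.ndarray]] = [(root, root_seq)]
    while stack:
        node, seq = stack.pop()
        if node.label is not None:
            out[node.label] = "".join(_BASES[seq])
            continue
        for child in node.children:
            branch = node.age - child.age
            stack.append((child, _jc69_evolve(seq, branch, rng)))
    return out


def evolve_locus(
    specimens: Sequence[SpecimenRecord],
    locus: LocusConfig,
    seed: int | np.random.Generator,
    between_plot_extra: float = 0.0,
) -> LocusAlignment | dict[str, LocusAlignment]:
    """Simulate one locus; returns per-family blocks when configured.

    Specimens failing the per-specimen recovery Bernoulli draw are left
    out of the alignment (they model sequencing failure).  With
    ``family_blocks`` each family gets an independent alignment in its
    own coordinate system, mimicking a locus that cannot be globally
    aligned across families.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    recovered = [s for s in specimens if rng.random() < locus.recovery_rate]
    if not recovered:
        raise ValidationError(f"{locus.name}: no specimens recovered; raise recovery_rate")
    if locus.family_blocks:
        blocks: dict[str, LocusAlignment] = {}
        for family in sorted({s.family for s in recovered}):
            fam_specs = [s for s in recovered if s.family == family]
            tree = build_locus_tree(fam_specs, locus, between_plot_extra, rng)
            seqs = _simulate_sequences(tree, locus.length, rng)
            members = [s.sample_id for s in fam_specs]
            blocks[family] = LocusAlignment(locus.name, members, [seqs[m] for m in members])
        return blocks
    tree = build_locus_tree(recovered, locus, between_plot_extra, rng)
    seqs = _simulate_sequences(tree, locus.length, rng)
    members = [s.sample_id for s in recovered]
    return LocusAlignment(locus.name, members, [seqs[m] for m in members])


# ---------------------------------------------------------------------------
# misidentification injection


def _largest_remainder(proportions: Sequence[float], total: int) -> list[int]:
    raw = np.asarray(proportions, dtype=float)
    raw = raw / raw.sum() * total
    counts = np.floor(raw).astype(int)
    short = total - int(counts.sum())
    order = np.argsort(-(raw - counts), kind="stable")
    for k in range(short):
        counts[order[k]] += 1
    return counts.tolist()


def inject_misidentifications(
    true_records: Sequence[SpecimenRecord],
    rate: float,
    level_mix: tuple[float, float, float],
    seed: int | np.random.Generator,
) -> tuple[list[SpecimenRecord], list[InjectedError]]:
    """Corrupt a fraction of specimen labels at family/genus/species level.

    A family-level error relabels a specimen with a species from a
    different family; genus-level keeps the family but changes the genus;
    species-level keeps the genus.  Counts per level follow the mix by
    largest remainder, so an exact mix over an exact total is reproduced
    exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    records = list(true_records)
    n_errors = int(round(rate * len(records)))
    if n_errors == 0:
        return records, []
    per_level = dict(zip(("family", "genus", "species"), _largest_remainder(level_mix, n_errors)))

    triples = sorted({(r.species, r.genus, r.family) for r in records})
    by_id = {r.sample_id: i for i, r in enumerate(records)}

    def donors(level: str, rec: SpecimenRecord) -> list[tuple[str, str, str]]:
        if level == "family":
            return [t for t in triples if t[2] != rec.family]
        if level == "genus":
            return [t for t in triples if t[2] == rec.family and t[1] != rec.genus]
        return [t for t in triples if t[1] == rec.genus and t[0] != rec.species]

    victims = [records[i].sample_id for i in rng.permutation(len(records))]
    used: set[str] = set()
    errors: list[InjectedError] = []
    for level in ("family", "genus", "species"):
        need = per_level[level]
        placed = 0
        for sid in victims:
            if placed >= need:
                break
            if sid in used:
                continue
            rec = records[by_id[sid]]
            cand = donors(level, rec)
            if not cand:
                continue
            sp, gn, fa = cand[int(rng.integers(len(cand)))]
            records[by_id[sid]] = replace(rec, species=sp, genus=gn, family=fa)
            errors.append(
                InjectedError(
                    sample_id=sid,
                    level=level,
                    true_species=rec.species,
                    true_genus=rec.genus,
                    true_family=rec.family,
                    recorded_species=sp,
                    recorded_genus=gn,
                    recorded_family=fa,
                )
            )
            used.add(sid)
            placed += 1
        if placed < need:
            raise ValidationError(
                f"cannot inject {need} {level}-level errors: only {placed} "
                "eligible specimen/donor combinations (taxonomy too small)"
            )
    errors.sort(key=lambda e: e.sample_id)
    return records, errors


def generate_dataset(config: SimConfig) -> tuple[Dataset, GroundTruth]:
    """Full pipeline input: taxonomy, per-locus alignments, injected errors.

    The Dataset carries the *recorded* (possibly corrupted) labels, as a
    field campaign would; the GroundTruth keeps the true ones.
    """
    ss = np.random.SeedSequence(config.seed)
    tax_rng, err_rng, *locus_rngs = [
        np.random.default_rng(s) for s in ss.spawn(2 + len(config.loci))
    ]
    true_records = generate_taxonomy(config, tax_rng)
    recorded, errors = inject_misidentifications(
        true_records, config.misid_rate, config.misid_level_mix, err_rng
    )
    recorded_family = {r.sample_id: r.family for r in recorded}
    alignments: dict[str, LocusAlignment | dict[str, LocusAlignment]] = {}
    for lc, rng in zip(config.loci, locus_rngs):
        aln = evolve_locus(true_records, lc, rng, config.between_plot_extra)
        if isinstance(aln, dict):
            # family blocks are organised by the *recorded* family: a
            # misidentified specimen would have been aligned with the
            # family it was (wrongly) assigned to in the field
            regrouped: dict[str, tuple[list[str], list[str]]] = {}
            for block in aln.values():
                for sid, row in zip(block.members, block.rows):
                    fam = recorded_family[sid]
                    members, rows = regrouped.setdefault(fam, ([], []))
                    members.append(sid)
                    rows.append(row)
            aln = {
                fam: LocusAlignment(lc.name, members, rows)
                for fam, (members, rows) in sorted(regrouped.items())
            }
        alignments[lc.name] = aln
    dataset = Dataset(recorded, alignments)
    truth = GroundTruth(true_records, recorded, errors)
    return dataset, truth
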