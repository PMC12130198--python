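"""Synthetic cohort generator with planted, documented effects.

Everything the pipeline consumes can be generated here at toy scale:
five-to-six small bacterial models sharing one metabolite namespace, a
longitudinal patient cohort with disease-activity trajectories,
abundance tables whose butyrate-producer component declines with
disease activity, a ~60-reaction host model over eight subsystems with
GPR rules, negative-binomial expression counts with designated
reactions coupled to disease activity, log-normal serum metabolite
concentrations with planted effects, and a diet covering all community
uptake needs.

Planted mechanisms (recorded in :class:`GroundTruth`):

* the butyrate producer's relative abundance declines with disease
  score, so the community's butyrate host exchange is negatively
  associated with inflammation;
* each bacterial template has a single catabolic route, so member
  fluxes are uniquely determined by member growth and community
  optima are vertex-unique (exchange fluxes are comparable across
  runs);
* community growth is limited by the lactate supply (generalist and
  cross-feeder both consume it), so doubling dietary lactate raises
  community growth and with it butyrate secretion — the planted
  "desired" dietary intervention;
* host genes of one subsystem go down and of another go up with
  disease score; serum butyrate and tryptophan fall, cholate rises.

All draws come from one seeded generator; outputs are byte-identical
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .community import CommunityMember, Diet
from .core import Gpr, MetabolicModel, Metabolite, Reaction

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "TEMPLATES",
    "make_toy_bacterium",
    "taxonomy_of",
    "random_network",
    "make_cohort",
    "make_host_model_and_expression",
    "make_metabolomics_and_diet",
    "make_default_diet",
    "SyntheticCohort",
    "make_all",
]


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_patients: int = 20
    n_timepoints: int = 4
    timepoints: tuple[float, ...] = (0.0, 2.0, 6.0, 14.0)
    taxa: tuple[str, ...] = (
        "butyrate_producer",
        "lactate_crossfeeder",
        "amino_acid_producer",
        "bile_deconjugator",
        "generalist",
        "starch_degrader",
    )
    abundance_score_slope: float = -0.18   # butyrate producer, logit/score unit
    abundance_patient_sd: float = 0.3
    abundance_noise_sd: float = 0.2
    expression_score_beta: float = 0.08    # log-mean shift per score unit
    expression_patient_sd: float = 0.3
    expression_dispersion: float = 0.1
    metabolome_score_beta: float = 0.06
    metabolome_noise_sd: float = 0.25
    missing_score_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.n_timepoints != len(self.timepoints):
            raise ValueError("n_timepoints must match timepoints")


@dataclass
class GroundTruth:
    """Planted-positive features (layer, feature, sign) and planted
    nulls (layer, feature); plus the planted desired intervention."""

    planted: list[tuple[str, str, int]] = field(default_factory=list)
    nulls: list[tuple[str, str]] = field(default_factory=list)
    intervention: tuple[str, str, str, str] = ("lac", "double", "but", "host_exchange")

    def to_frame(self) -> pd.DataFrame:
        rows = [(l, f, s, "planted") for l, f, s in self.planted]
        rows += [(l, f, 0, "null") for l, f in self.nulls]
        return pd.DataFrame(rows, columns=["layer", "feature", "sign", "status"])


# ---------------------------------------------------------------------------
# Toy bacteria
# ---------------------------------------------------------------------------

# template -> (substrates with uptake stoich, products per unit catabolic
# flux, biomass yield per unit catabolic flux)
TEMPLATES: dict[str, dict] = {
    "butyrate_producer": dict(
        substrates={"glc": 1.0, "nh4": 0.3},
        products={"but": 0.6, "lac": 0.3, "ac": 0.3},
        biomass_yield=0.45,
        taxonomy={"phylum": "Firmicutes", "class": "Clostridia",
                  "family": "Lachnospiraceae", "genus": "Roseburia",
                  "species": "Roseburia synthetica"},
    ),
    "lactate_crossfeeder": dict(
        substrates={"lac": 1.0, "nh4": 0.2},
        products={"ppa": 0.7},
        biomass_yield=0.35,
        taxonomy={"phylum": "Firmicutes", "class": "Negativicutes",
                  "family": "Veillonellaceae", "genus": "Veillonella",
                  "species": "Veillonella synthetica"},
    ),
    "amino_acid_producer": dict(
        substrates={"glc": 1.0, "nh4": 0.5},
        products={"trp": 0.3, "ind": 0.2},
        biomass_yield=0.4,
        taxonomy={"phylum": "Proteobacteria", "class": "Gammaproteobacteria",
                  "family": "Enterobacteriaceae", "genus": "Escherichia",
                  "species": "Escherichia synthetica"},
    ),
    "bile_deconjugator": dict(
        substrates={"glc": 0.8, "tchola": 0.5, "nh4": 0.2},
        products={"chola": 0.5, "ac": 0.4},
        biomass_yield=0.35,
        taxonomy={"phylum": "Actinobacteriota", "class": "Actinomycetia",
                  "family": "Bifidobacteriaceae", "genus": "Bifidobacterium",
                  "species": "Bifidobacterium synthetica"},
    ),
    "generalist": dict(
        substrates={"lac": 1.0, "nh4": 0.2},
        products={"ac": 0.6},
        biomass_yield=0.3,
        taxonomy={"phylum": "Bacteroidota", "class": "Bacteroidia",
                  "family": "Bacteroidaceae", "genus": "Bacteroides",
                  "species": "Bacteroides syntheticus"},
    ),
    "starch_degrader": dict(
        substrates={"starch": 1.0, "nh4": 0.2},
        products={"glc": 1.2, "ac": 0.2},
        biomass_yield=0.3,
        taxonomy={"phylum": "Bacteroidota", "class": "Bacteroidia",
                  "family": "Rikenellaceae", "genus": "Alistipes",
                  "species": "Alistipes syntheticus"},
    ),
}

UPTAKE_BOUND = 20.0


def make_toy_bacterium(
    template: str, rng: np.random.Generator | None = None
) -> MetabolicModel:
    """Build one template bacterium: uptake exchanges + transporters, a
    single catabolic reaction, secretion transport + exchanges, and a
    biomass reaction (the objective).

    The single catabolic route makes every internal flux a fixed
    multiple of the growth rate, so community optima are unique.  A
    seeded ``rng`` jitters the yield coefficients by up to 5%."""
    if template not in TEMPLATES:
        raise ValueError(f"unknown template {template!r}; use {sorted(TEMPLATES)}")
    spec = TEMPLATES[template]
    jitter = (lambda x: x) if rng is None else (
        lambda x: x * float(1 + rng.uniform(-0.05, 0.05))
    )
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []

    # external metabolites keep the base id (shared namespace with the
    # diet, the environment compartment, and the other data layers)
    def ext(m: str) -> str:
        return m

    def cyt(m: str) -> str:
        return f"{m}_c"

    used: set[str] = set()

    def ensure(mid: str, comp: str) -> None:
        if mid not in used:
            used.add(mid)
            mets.append(Metabolite(mid, name=mid, compartment=comp))

    cat_stoich: dict[str, float] = {}
    for m, coeff in spec["substrates"].items():
        ensure(ext(m), "e")
        ensure(cyt(m), "c")
        rxns.append(Reaction(f"EX_{m}", {ext(m): -1.0}, -UPTAKE_BOUND, 1000.0))
        rxns.append(Reaction(f"T_{m}_in", {ext(m): -1.0, cyt(m): 1.0}, 0.0, UPTAKE_BOUND))
        cat_stoich[cyt(m)] = -coeff
    for m, coeff in spec["products"].items():
        ensure(ext(m), "e")
        ensure(cyt(m), "c")
        rxns.append(Reaction(f"T_{m}_out", {cyt(m): -1.0, ext(m): 1.0}, 0.0, 1000.0))
        if f"EX_{m}" not in {r.id for r in rxns}:
            rxns.append(Reaction(f"EX_{m}", {ext(m): -1.0}, 0.0, 1000.0))
        cat_stoich[cyt(m)] = cat_stoich.get(cyt(m), 0.0) + jitter(coeff)
    ensure("bm_pre_c", "c")
    cat_stoich["bm_pre_c"] = jitter(spec["biomass_yield"])
    rxns.append(Reaction("CATABOLISM", cat_stoich, 0.0, UPTAKE_BOUND))
    rxns.append(Reaction("BIOMASS", {"bm_pre_c": -1.0}, 0.0, 1000.0))
    return MetabolicModel(
        id=template, metabolites=mets, reactions=rxns, objective="BIOMASS"
    )


def taxonomy_of(template: str) -> dict[str, str]:
    return dict(TEMPLATES[template]["taxonomy"])


def make_default_diet() -> Diet:
    """Diet covering every community uptake need.

    Lactate is kept scarce while every other nutrient is generous, so
    the lactate consumers' demand is the binding community resource
    across the whole range of plausible compositions.  That keeps the
    planted mechanisms structural: butyrate output tracks the butyrate
    producer's abundance (never the inverse, which would happen if a
    butyrate-producer-dominated resource like glucose were limiting),
    and doubling dietary lactate raises community growth."""
    return Diet(
        {"glc": 30.0, "starch": 4.0, "lac": 2.0, "nh4": 50.0,
         "tchola": 5.0, "trp": 2.0},
        name="synthetic_diet",
    )


def random_network(
    rng: np.random.Generator,
    n_reactions: int = 15,
    n_exchanges: int | None = None,
) -> MetabolicModel:
    """Random stoichiometric network for oracle comparisons.

    Roughly half the metabolites get an exchange reaction (open in both
    directions) and the internal reactions convert 1-2 random
    substrates into 1-2 random products; ~30% are reversible.  The
    networks are deliberately messy: some reactions end up blocked,
    which is what the blocked-reaction and FASTCORE oracles need."""
    n_mets = max(3, n_reactions // 2 + 2)
    mets = [Metabolite(f"m{i}", compartment="c") for i in range(n_mets)]
    n_ex = n_exchanges if n_exchanges is not None else max(2, n_mets // 2)
    rxns: list[Reaction] = []
    for i in range(min(n_ex, n_mets)):
        rxns.append(Reaction(f"EX_m{i}", {f"m{i}": -1.0}, -10.0, 10.0))
    k = 0
    while len(rxns) < n_reactions:
        ns = int(rng.integers(1, 3))
        np_ = int(rng.integers(1, 3))
        picks = rng.choice(n_mets, size=ns + np_, replace=False)
        stoich: dict[str, float] = {}
        for m in picks[:ns]:
            stoich[f"m{m}"] = -float(rng.integers(1, 3))
        for m in picks[ns:]:
            stoich[f"m{m}"] = float(rng.integers(1, 3))
        lb = -10.0 if rng.random() < 0.3 else 0.0
        rxns.append(Reaction(f"R{k}", stoich, lb, 10.0))
        k += 1
    return MetabolicModel(id="random", metabolites=mets, reactions=rxns)


# ---------------------------------------------------------------------------
# Cohort: metadata + abundances
# ---------------------------------------------------------------------------

def make_cohort(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Patient metadata (with raw, uncensored, partly missing disease
    scores), a taxa x sample abundance table, and the microbial part of
    the ground truth."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    kinds = np.array(
        ["healthy"] * max(1, n // 5)
        + ["responder"] * max(1, n // 2)
        + ["nonresponder"] * n
    )[:n]
    records = []
    latent: dict[str, float] = {}
    for i in range(n):
        pat = f"P{i + 1:02d}"
        kind = kinds[i]
        sex = "F" if rng.random() < 0.5 else "M"
        age = int(rng.integers(20, 70))
        seqtype = "A" if rng.random() < 0.5 else "B"
        if kind == "healthy":
            base = rng.uniform(0.0, 3.0)
            traj = base + rng.normal(0, 0.5, len(cfg.timepoints))
        elif kind == "responder":
            s0 = rng.uniform(10.0, 19.0)
            traj = s0 * np.exp(-np.asarray(cfg.timepoints) / 6.0)
            traj = traj + rng.normal(0, 1.0, len(traj))
        else:
            s0 = rng.uniform(8.0, 19.0)
            traj = s0 + rng.normal(0, 1.0, len(cfg.timepoints))
        traj = np.clip(traj, 0.0, 22.0)
        final = traj[-1]
        response = "yes" if kind == "responder" else ("NA" if kind == "healthy" else "no")
        remission = "yes" if final < 5.0 else "no"
        if kind == "healthy":
            remission = "NA"
        for t, score in zip(cfg.timepoints, traj):
            sid = f"{pat}_t{int(t):02d}"
            latent[sid] = min(score, 16.0)
            observed: float | None = float(score)
            if rng.random() < cfg.missing_score_rate and t != cfg.timepoints[0]:
                observed = np.nan
            records.append(
                (sid, pat, t, "stool", observed, response, remission,
                 seqtype, sex, age)
            )
    md = pd.DataFrame(
        records,
        columns=["sample", "patient", "time", "source", "disease_score",
                 "response", "remission", "seqtype", "sex", "age"],
    ).set_index("sample")

    # abundances: logistic-normal with planted decline of the butyrate
    # producer; patient-level intercepts give temporal autocorrelation
    taxa = list(cfg.taxa)
    base_logit = {
        "butyrate_producer": 0.8,
        "lactate_crossfeeder": 0.4,
        "amino_acid_producer": 0.0,
        "bile_deconjugator": -0.3,
        "generalist": 1.0,
        "starch_degrader": 0.2,
    }
    pat_re = {
        (p, tx): rng.normal(0, cfg.abundance_patient_sd)
        for p in md["patient"].unique()
        for tx in taxa
    }
    rows = {}
    for sid, row in md.iterrows():
        score = latent[sid]
        logits = []
        for tx in taxa:
            lg = base_logit.get(tx, 0.0) + pat_re[(row["patient"], tx)]
            lg += rng.normal(0, cfg.abundance_noise_sd)
            if tx == "butyrate_producer":
                lg += cfg.abundance_score_slope * (score - 8.0)
            logits.append(lg)
        ex = np.exp(np.asarray(logits) - max(logits))
        rows[sid] = ex / ex.sum()
    abundances = pd.DataFrame(rows, index=taxa)

    gt = GroundTruth()
    gt.planted.append(("micro_exchange_host", "but", -1))
    md.attrs["latent_score"] = latent
    return md, abundances, gt


# ---------------------------------------------------------------------------
# Host model + expression
# ---------------------------------------------------------------------------

HOST_SUBSYSTEMS = (
    "Glycolysis",
    "TCA cycle",
    "Oxidative phosphorylation",
    "Fatty acid synthesis",
    "Amino acid metabolism",
    "Bile acid metabolism",
    "Nucleotide metabolism",
    "Sphingolipid metabolism",
)
PLANTED_DOWN_SUBSYSTEM = "Oxidative phosphorylation"
PLANTED_UP_SUBSYSTEM = "Fatty acid synthesis"
NULL_SUBSYSTEMS = ("Nucleotide metabolism", "Sphingolipid metabolism")

# chain entry metabolites tie the host namespace to the microbial /
# metabolomics namespaces (identity mapping across layers)
_CHAIN_ENTRY = {
    "Glycolysis": "glc",
    "TCA cycle": "ac",
    "Oxidative phosphorylation": "but",
    "Fatty acid synthesis": "ppa",
    "Amino acid metabolism": "trp",
    "Bile acid metabolism": "chola",
    "Nucleotide metabolism": "nuc0",
    "Sphingolipid metabolism": "sph0",
}


def make_host_model_and_expression(
    cfg: SyntheticConfig,
    metadata: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[MetabolicModel, pd.DataFrame, pd.Series, GroundTruth]:
    """~64-reaction host model (8 subsystems x linear chain of 5 GPR
    reactions each, plus entry exchange and terminal demand) and
    negative-binomial counts whose planted subsystems' genes track the
    disease score with patient random intercepts."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    gene_beta: dict[str, float] = {}
    gt = GroundTruth()

    chain_len = 5
    for k, sub in enumerate(HOST_SUBSYSTEMS):
        entry = _CHAIN_ENTRY[sub]
        nodes = [entry] + [f"{entry}_m{j}" for j in range(1, chain_len + 1)]
        for m in nodes:
            mets.append(Metabolite(m, name=m, compartment="c"))
        rxns.append(Reaction(f"EX_{entry}", {entry: -1.0}, -50.0, 1000.0,
                             subsystem=sub))
        beta = 0.0
        sign = 0
        if sub == PLANTED_DOWN_SUBSYSTEM:
            beta, sign = -cfg.expression_score_beta, -1
        elif sub == PLANTED_UP_SUBSYSTEM:
            beta, sign = cfg.expression_score_beta, 1
        for j in range(chain_len):
            rid = f"R_{k}_{j}"
            genes = [f"G_{k}_{j}_{suf}" for suf in "abc"]
            pattern = j % 4
            if pattern == 0:
                gpr = Gpr("gene", gene=genes[0])
                active = genes[:1]
            elif pattern == 1:
                gpr = Gpr("or", children=(Gpr("gene", gene=genes[0]),
                                          Gpr("gene", gene=genes[1])))
                active = genes[:2]
            elif pattern == 2:
                gpr = Gpr("and", children=(Gpr("gene", gene=genes[0]),
                                           Gpr("gene", gene=genes[1])))
                active = genes[:2]
            else:
                gpr = Gpr("and", children=(
                    Gpr("or", children=(Gpr("gene", gene=genes[0]),
                                        Gpr("gene", gene=genes[1]))),
                    Gpr("gene", gene=genes[2]),
                ))
                active = genes
            for g in active:
                gene_beta[g] = beta
            rxns.append(Reaction(rid, {nodes[j]: -1.0, nodes[j + 1]: 1.0},
                                 0.0, 1000.0, gpr=gpr, subsystem=sub))
            if sign != 0:
                gt.planted.append(("host_reaction", rid, sign))
            elif sub in NULL_SUBSYSTEMS:
                gt.nulls.append(("host_reaction", rid))
        rxns.append(Reaction(f"DM_{entry}", {nodes[-1]: -1.0}, 0.0, 1000.0,
                             subsystem=sub))
    host = MetabolicModel("synthetic_host", mets, rxns, objective="")

    genes = sorted(gene_beta)
    # a few expressed genes that no GPR references (ignored downstream)
    extra = [f"G_extra_{i}" for i in range(6)]
    all_genes = genes + extra
    lengths = pd.Series(rng.integers(500, 3000, len(all_genes)).astype(float),
                        index=all_genes, name="length")
    base = rng.normal(np.log(200.0), 0.5, len(all_genes))
    latent = metadata.attrs["latent_score"]
    pat_re = {
        (p, g): rng.normal(0, cfg.expression_patient_sd)
        for p in metadata["patient"].unique()
        for g in all_genes
    }
    disp = cfg.expression_dispersion
    size = 1.0 / disp
    counts = {}
    for sid, row in metadata.iterrows():
        score = latent[sid]
        mu = np.array([
            np.exp(base[i] + gene_beta.get(g, 0.0) * (score - 8.0)
                   + pat_re[(row["patient"], g)])
            * lengths[g] / 1000.0
            for i, g in enumerate(all_genes)
        ])
        p = size / (size + mu)
        counts[sid] = rng.negative_binomial(size, p)
    counts_df = pd.DataFrame(counts, index=all_genes)
    return host, counts_df, lengths, gt


# ---------------------------------------------------------------------------
# Metabolomics + diet
# ---------------------------------------------------------------------------

PLANTED_METABOLITES = {"but": -1, "trp": -1, "chola": 1}


def make_metabolomics_and_diet(
    cfg: SyntheticConfig,
    metadata: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, Diet, GroundTruth]:
    """Log-normal serum concentrations: three planted disease-linked
    metabolites overlapping the shared namespace plus null serum
    markers; and the standard synthetic diet."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    null_mets = [f"ser_{i:02d}" for i in range(15)]
    mets = list(PLANTED_METABOLITES) + null_mets
    latent = metadata.attrs["latent_score"]
    base = rng.normal(np.log(50.0), 0.4, len(mets))
    pat_re = {
        (p, m): rng.normal(0, 0.15)
        for p in metadata["patient"].unique()
        for m in mets
    }
    rows = {}
    for sid, row in metadata.iterrows():
        score = latent[sid]
        vals = []
        for i, m in enumerate(mets):
            beta = PLANTED_METABOLITES.get(m, 0) * cfg.metabolome_score_beta
            logv = (base[i] + beta * (score - 8.0)
                    + pat_re[(row["patient"], m)]
                    + rng.normal(0, cfg.metabolome_noise_sd))
            vals.append(np.exp(logv))
        rows[sid] = vals
    conc = pd.DataFrame(rows, index=mets)
    gt = GroundTruth()
    for m, s in PLANTED_METABOLITES.items():
        gt.planted.append(("metabolomics", m, s))
    for m in null_mets:
        gt.nulls.append(("metabolomics", m))
    return conc, make_default_diet(), gt


# ---------------------------------------------------------------------------
# One-call cohort bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    metadata: pd.DataFrame
    abundances: pd.DataFrame
    models: dict[str, MetabolicModel]
    host: MetabolicModel
    counts: pd.DataFrame
    gene_lengths: pd.Series
    metabolome: pd.DataFrame
    diet: Diet
    truth: GroundTruth

    def members_for_sample(self, sample: str) -> list[CommunityMember]:
        ab = self.abundances[sample]
        return [
            CommunityMember(self.models[t], float(ab[t]), taxonomy_of(t))
            for t in self.abundances.index
        ]


def make_all(cfg: SyntheticConfig = SyntheticConfig()) -> SyntheticCohort:
    rng = np.random.default_rng(cfg.seed)
    metadata, abundances, gt_micro = make_cohort(cfg, rng)
    models = {t: make_toy_bacterium(t, rng) for t in cfg.taxa}
    host, counts, lengths, gt_host = make_host_model_and_expression(cfg, metadata, rng)
    metabolome, diet, gt_met = make_metabolomics_and_diet(cfg, metadata, rng)
    truth = GroundTruth(
        planted=gt_micro.planted + gt_host.planted + gt_met.planted,
        nulls=gt_micro.nulls + gt_host.nulls + gt_met.nulls,
    )
    return SyntheticCohort(
        config=cfg, metadata=metadata, abundances=abundances, models=models,
        host=host, counts=counts, gene_lengths=lengths, metabolome=metabolome,
        diet=diet, truth=truth,
    )


def write_all(cohort: SyntheticCohort, outdir) -> None:
    """Write the cohort as TSV/JSON files (the CLI entry point)."""
    import os

    from .core import write_model

    os.makedirs(outdir, exist_ok=True)
    j = lambda *p: os.path.join(outdir, *p)
    cohort.metadata.to_csv(j("metadata.tsv"), sep="\t")
    cohort.abundances.to_csv(j("abundances.tsv"), sep="\t")
    cohort.counts.to_csv(j("counts.tsv"), sep="\t")
    cohort.gene_lengths.to_frame().to_csv(j("gene_lengths.tsv"), sep="\t")
    cohort.metabolome.to_csv(j("metabolome.tsv"), sep="\t")
    cohort.diet.to_tsv(j("diet.tsv"))
    cohort.truth.to_frame().to_csv(j("ground_truth.tsv"), sep="\t", index=False)
    os.makedirs(j("models"), exist_ok=True)
    for name, model in cohort.models.items():
        write_model(model, j("models", f"{name}.json"))
    write_model(cohort.host, j("host_model.json"))
    tax = pd.DataFrame(
        {t: taxonomy_of(t) for t in cohort.abundances.index}
    ).T
    tax.index.name = "taxon"
    tax.to_csv(j("taxonomy.tsv"), sep="\t")
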