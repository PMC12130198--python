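"""End-to-end orchestration of the analysis stages.

Stage order: synthetic data (or user inputs) -> per-sample community
simulation (coupled LP and agent arena) -> context-specific host
models and reaction layers -> per-layer longitudinal associations ->
metabolite network paths -> dietary intervention screen -> report.

The pipeline runs in memory on a :class:`~gutflux.synth.SyntheticCohort`
and writes every result table as TSV; a :class:`RunManifest` records
the configuration hash and output checksums so deterministic stages
can be verified to reproduce bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._lp import OPTIMAL
from .agents import AgentConfig, run_agent_simulation
from .community import (
    CouplingConfig,
    assemble_community,
    decompose_exchanges,
    screen_members,
    simulate_community,
)
from .context import (
    ThresholdConfig,
    build_core_sets,
    compute_reaction_layers,
    counts_to_tpm,
    extract_context_model,
    reaction_expression,
)
from .interventions import (
    FC_THRESHOLD,
    run_intervention_screen,
    select_targets,
    summarize_interventions,
)
from .network import (
    CategoryLabels,
    all_pairs_distances,
    build_metabolite_graph,
    compare_category_paths,
    enrich_path_reactions,
    select_short_pairs,
)
from .stats import (
    LayerAssociation,
    PreprocessConfig,
    enrich_hypergeometric,
    metabolite_reaction_sets,
    prepare_metadata,
    preprocess_features,
)
from .synth import SyntheticCohort, SyntheticConfig, make_all, write_all

log = logging.getLogger(__name__)

MICRO_LAYERS = ("micro_exchange_host", "micro_exchange_community")
HOST_LAYERS = ("rxnExpr", "PA", "FVA.range", "FVA.center")


@dataclass
class PipelineConfig:
    outdir: str = "gutflux_run"
    seed: int = 0
    alpha: float = 0.05
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    # the synthetic run uses a scaled-down arena; AgentConfig defaults
    # keep the full-study geometry
    agent: AgentConfig = field(
        default_factory=lambda: AgentConfig(grid=(20, 20), capacity=40)
    )
    fc_threshold: float = FC_THRESHOLD
    path_percentile: float = 5.0
    covariates: tuple[str, ...] = ()
    run_agent: bool = True
    run_outcome_models: bool = True

    def hash(self) -> str:
        payload = json.dumps(_as_jsonable(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    return obj


@dataclass
class RunManifest:
    config_hash: str
    checksums: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)

    def record(self, path: str) -> None:
        with open(path, "rb") as fh:
            self.checksums[os.path.basename(path)] = hashlib.sha256(
                fh.read()
            ).hexdigest()

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"config_hash": self.config_hash, "checksums": self.checksums,
                 "timings": self.timings},
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")


@dataclass
class PipelineResult:
    cohort: SyntheticCohort
    metadata: pd.DataFrame
    feature_layers: dict[str, pd.DataFrame]
    associations: dict[str, "object"]          # layer -> AssociationResult
    outcome_associations: dict[tuple[str, str], "object"]
    enrichment: dict[str, pd.DataFrame]
    network_tables: dict[str, pd.DataFrame]
    interventions: pd.DataFrame
    manifest: RunManifest


def _tsv(manifest: RunManifest, df: pd.DataFrame, path: str, **kw) -> None:
    df.to_csv(path, sep="\t", **kw)
    manifest.record(path)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest = RunManifest(config_hash=cfg.hash())
    t0 = time.time()

    # --- stage: synthetic data -------------------------------------
    cohort = make_all(dataclasses.replace(cfg.synthetic, seed=cfg.seed))
    write_all(cohort, os.path.join(cfg.outdir, "data"))
    metadata = prepare_metadata(cohort.metadata.reset_index(), score_col="disease_score",
                                patient_col="patient", time_col="time").set_index("sample")
    manifest.timings["simulate_data"] = time.time() - t0

    # --- stage: community simulation -------------------------------
    t = time.time()
    host_ex: dict[str, dict[str, float]] = {}
    comm_ex: dict[str, dict[str, float]] = {}
    agent_ex: dict[str, dict[str, float]] = {}
    communities = {}
    taxon_rows = []
    for sid in metadata.index:
        members = screen_members(cohort.members_for_sample(sid), cohort.diet,
                                 cfg.coupling)
        cm = assemble_community(members, cohort.diet, cfg.coupling)
        sol = simulate_community(cm)
        if sol.status != OPTIMAL:
            log.warning("sample %s: community infeasible", sid)
            continue
        communities[sid] = cm
        summ = decompose_exchanges(cm, sol)
        host_ex[sid] = summ.host_exchange
        comm_ex[sid] = summ.microbial_exchange
        for met in summ.host_exchange:
            for mem in cm.members:
                var = cm.internal_exchange_vars.get((mem.id, met))
                if var is None:
                    continue
                taxon_rows.append(
                    (sid, metadata.loc[sid, "patient"], met,
                     mem.taxonomy.get("class", ""), sol.fluxes[var])
                )
        if cfg.run_agent:
            agent_cfg = dataclasses.replace(cfg.agent, seed=cfg.seed)
            asum = run_agent_simulation(members, cohort.diet, agent_cfg)
            agent_ex[sid] = asum.host_exchange
    layers: dict[str, pd.DataFrame] = {
        "micro_exchange_host": pd.DataFrame(host_ex),
        "micro_exchange_community": pd.DataFrame(comm_ex),
    }
    if cfg.run_agent:
        layers["agent_exchange_host"] = pd.DataFrame(agent_ex)
    taxon_fluxes = pd.DataFrame(
        taxon_rows, columns=["sample", "patient", "metabolite", "taxon", "flux"]
    )
    manifest.timings["community"] = time.time() - t

    # --- stage: context-specific host models ------------------------
    t = time.time()
    tpm = counts_to_tpm(cohort.counts, cohort.gene_lengths)
    scores = reaction_expression(cohort.host, tpm)
    core_sets = build_core_sets(scores, cfg.thresholds)
    context_models = {}
    for sid in scores.columns:
        if sid not in metadata.index:
            continue
        try:
            context_models[sid] = extract_context_model(
                cohort.host, core_sets.core[sid], core_sets.inactive[sid],
                sample=sid,
            )
        except Exception as exc:
            log.warning("context model failed for %s: %s", sid, exc)
    rl = compute_reaction_layers(context_models, scores)
    layers.update(rl.as_dict())
    manifest.timings["context_models"] = time.time() - t

    # --- stage: associations ----------------------------------------
    t = time.time()
    associations = {}
    preprocessed = {}
    for name, mat in layers.items():
        mat = mat.dropna(axis=1, how="all")
        mat = mat.loc[:, [s for s in mat.columns if s in metadata.index]]
        filled = mat.fillna(0.0)
        try:
            prep = preprocess_features(filled, cfg.preprocess)
        except ValueError as exc:
            log.warning("layer %s skipped: %s", name, exc)
            continue
        if prep.features.empty:
            continue
        preprocessed[name] = prep
        res = LayerAssociation(
            prep.features, metadata, covariates=cfg.covariates
        ).fit(layer=name)
        # cluster members inherit the representative's result (sign-aware)
        res.table = prep.expand(res.table)
        associations[name] = res

    # metabolomics layer
    prep_met = preprocess_features(cohort.metabolome.loc[
        :, [s for s in cohort.metabolome.columns if s in metadata.index]
    ], cfg.preprocess)
    res = LayerAssociation(prep_met.features, metadata).fit(layer="metabolomics")
    res.table = prep_met.expand(res.table)
    associations["metabolomics"] = res

    outcome_associations = {}
    if cfg.run_outcome_models:
        for outcome in ("response", "remission"):
            for lname in ("micro_exchange_host",):
                if lname not in preprocessed:
                    continue
                outcome_associations[(lname, outcome)] = LayerAssociation(
                    preprocessed[lname].features, metadata, outcome=outcome,
                    control_disease_activity=True,
                ).fit(layer=lname)
    manifest.timings["associations"] = time.time() - t

    # --- stage: enrichment -------------------------------------------
    t = time.time()
    enrichment: dict[str, pd.DataFrame] = {}
    subsystem_of = {r.id: r.subsystem for r in cohort.host.reactions}
    host_effect = pd.concat(
        [associations[l].table["t_value"] for l in HOST_LAYERS if l in associations],
        axis=1,
    ).mean(axis=1).dropna()
    sig_host = set()
    for l in HOST_LAYERS:
        if l in associations:
            sig_host |= set(associations[l].significant(cfg.alpha).index)
    subsystem_sets: dict[str, set[str]] = {}
    for rid, sub in subsystem_of.items():
        if sub:
            subsystem_sets.setdefault(sub, set()).add(rid)
    universe = set(subsystem_of)
    enrichment["host_subsystems"] = enrich_hypergeometric(
        sig_host, subsystem_sets, universe
    )
    met_sets = metabolite_reaction_sets(cohort.host)
    enrichment["hub_metabolites"] = enrich_hypergeometric(
        sig_host, met_sets, universe
    )
    manifest.timings["enrichment"] = time.time() - t

    # --- stage: network ----------------------------------------------
    t = time.time()
    network_tables: dict[str, pd.DataFrame] = {}
    if sig_host:
        graph = build_metabolite_graph(sig_host, cohort.host)
        dists = all_pairs_distances(graph)
        hub = set(
            enrichment["hub_metabolites"]
            [enrichment["hub_metabolites"]["p_adj"] < cfg.alpha].index
        )
        mic_sig = (
            set(associations["micro_exchange_host"].significant(cfg.alpha).index)
            if "micro_exchange_host" in associations else set()
        )
        met_sig = set(associations["metabolomics"].significant(cfg.alpha).index)
        labels = CategoryLabels(hub=hub, mic=mic_sig, met=met_sig).restrict(
            set(graph.nodes)
        )
        network_tables["distances"] = dists
        network_tables["selected_pairs"] = select_short_pairs(
            dists, labels, cfg.path_percentile
        )
        network_tables["category_tests"] = compare_category_paths(dists, labels)
        if not network_tables["selected_pairs"].empty:
            network_tables["path_enrichment"] = enrich_path_reactions(
                network_tables["selected_pairs"], graph, subsystem_of
            )
    manifest.timings["network"] = time.time() - t

    # --- stage: interventions ----------------------------------------
    t = time.time()
    tables = {}
    for lname, method in (("micro_exchange_host", "coupling"),
                          ("micro_exchange_community", "coupling_community"),
                          ("agent_exchange_host", "agent")):
        if lname not in associations:
            continue
        tab = associations[lname].table.copy()
        scope = ("community_exchange" if lname == "micro_exchange_community"
                 else "host_exchange")
        tab.index = pd.MultiIndex.from_tuples([(scope, m) for m in tab.index])
        tables[(method, "activity")] = tab
    targets = select_targets(tables, alpha=cfg.alpha)
    interventions = pd.DataFrame()
    if targets and communities:
        screen = run_intervention_screen(communities, targets)
        interventions = summarize_interventions(
            screen, fc_threshold=cfg.fc_threshold, alpha=cfg.alpha
        )
    manifest.timings["interventions"] = time.time() - t

    # --- stage: report -----------------------------------------------
    export_report(
        cfg, manifest, metadata, layers, associations, outcome_associations,
        enrichment, network_tables, interventions, taxon_fluxes,
    )
    manifest.timings["total"] = time.time() - t0
    manifest.write(os.path.join(cfg.outdir, "manifest.json"))
    return PipelineResult(
        cohort=cohort, metadata=metadata, feature_layers=layers,
        associations=associations, outcome_associations=outcome_associations,
        enrichment=enrichment, network_tables=network_tables,
        interventions=interventions, manifest=manifest,
    )


def export_report(cfg, manifest, metadata, layers, associations,
                  outcome_associations, enrichment, network_tables,
                  interventions, taxon_fluxes) -> None:
    """TSV bundle mirroring the supplementary-table shapes."""
    out = cfg.outdir
    os.makedirs(os.path.join(out, "results"), exist_ok=True)
    j = lambda *p: os.path.join(out, "results", *p)
    _tsv(manifest, metadata, j("metadata_prepared.tsv"))
    for name, mat in layers.items():
        _tsv(manifest, mat, j(f"layer_{name.replace('.', '_')}.tsv"))
    for name, res in associations.items():
        _tsv(manifest, res.table, j(f"association_{name.replace('.', '_')}.tsv"))
    for (lname, outcome), res in outcome_associations.items():
        _tsv(manifest, res.table, j(f"association_{lname}_{outcome}.tsv"))
    for name, df in enrichment.items():
        _tsv(manifest, df, j(f"enrichment_{name}.tsv"))
    for name, df in network_tables.items():
        _tsv(manifest, df, j(f"network_{name}.tsv"), index=False)
    if interventions is not None and len(interventions):
        _tsv(manifest, interventions, j("interventions.tsv"), index=False)
    else:
        pd.DataFrame(columns=[
            "intervention", "mode", "target", "scope", "target_sign", "n",
            "n_flip", "n_zero_baseline", "p", "fc", "median_change", "low_n",
            "p_adj", "class",
        ]).to_csv(j("interventions.tsv"), sep="\t", index=False)
        manifest.record(j("interventions.tsv"))
    _tsv(manifest, taxon_fluxes, j("taxon_fluxes.tsv"), index=False)
    with open(j("config_hash.txt"), "w") as fh:
        fh.write(manifest.config_hash + "\n")
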