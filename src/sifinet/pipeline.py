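"""End-to-end study orchestration.

``run_pipeline`` drives the full synthetic study: behavioral simulation
and PPI/PPNI stratification, the 2x2 time-frequency cluster ANOVA, TE
network inference on the odd-numbered trials, model-space construction,
and hierarchical model selection on the even-numbered trials — with
explicit seeds, per-stage timing, and a JSON manifest.  The odd/even
trial partition (1-based over the trial sequence) guarantees that the
exploratory (TE) and confirmatory (model selection) stages never see
the same data.

``run_connectivity_study`` is the connectivity core on its own:
ground-truth simulation, TE network recovery, triangle-constrained
pruning and BMS, returning the winning structure next to the generating
one.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import model_space as msp
from . import model_selection as msel
from . import synthetic as syn
from . import te as te_mod
from . import timefreq as tf
from .containers import TrialEnsemble
from .network import DirectedNetwork
from .te import EmbeddingParams

__all__ = ["RunConfig", "run_pipeline", "run_connectivity_study",
           "odd_even_split"]


@dataclass
class RunConfig:
    """Scalar knobs of the demo study; structured specs use module defaults."""

    seed: int = 1
    n_young: int = 6
    n_older: int = 6
    # connectivity simulation
    n_trials: int = 60
    sfreq: float = 300.0
    tmin: float = -1.0
    tmax: float = 0.62
    coupling_scale: float = 1.0          # scales all ground-truth couplings
    # TE estimation
    te_window_lo: float = -0.25
    te_window_hi: float = 0.075
    u_max: int = 8
    te_alpha: float = 0.05
    n_surrogates: int = 20
    k_ksg: int = 4
    stride: int = 1
    d_max: int = 2
    ragwitz_tol: float = 0.25
    support_fraction: float = 0.5
    # spectral model selection
    band_lo: float = 12.0
    band_hi: float = 25.0
    dcm_window_lo: float = -0.25
    dcm_window_hi: float = 0.075
    # time-frequency stage
    n_sensors: int = 16
    tf_n_trials: int = 20
    tf_effect_multiplier: float = 1.8    # older-adult beta amplitude factor
    cluster_alpha: float = 0.05
    n_perm: int = 1000
    # behavior
    p_illusion_young: float = 0.618
    p_illusion_older: float = 0.647
    between_subject_sd: float = 0.18
    run_tf_stage: bool = True
    run_behavior_stage: bool = True
    run_connectivity_stage: bool = True

    def to_flat(self, path) -> None:
        """Write the config as a flat ``key = value`` file."""
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_flat(cls, path) -> "RunConfig":
        kwargs = {}
        defaults = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, v = (s.strip() for s in line.split("=", 1))
            cur = getattr(defaults, k)
            if isinstance(cur, bool):
                kwargs[k] = v.lower() in ("1", "true", "yes")
            else:
                kwargs[k] = type(cur)(v)
        return cls(**kwargs)


def odd_even_split(n_trials: int) -> tuple[np.ndarray, np.ndarray]:
    """1-based odd/even partition of the trial sequence.

    Odd-numbered trials (1, 3, 5, ... -> indices 0, 2, 4, ...) feed TE
    estimation; even-numbered trials feed model selection.
    """
    idx = np.arange(n_trials)
    return idx[::2], idx[1::2]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_connectivity_study(
    seed: int,
    net: syn.GroundTruthNetwork | None = None,
    n_subjects: int = 12,
    n_trials: int = 60,
    config: RunConfig | None = None,
    subject_cells: pd.DataFrame | None = None,
    illusion_rates: dict[str, float] | None = None,
    modulation_by_group: dict[str, dict] | None = None,
) -> dict:
    """Simulate sources, infer the TE network, prune and select models.

    Returns a dict with the ground truth, per-subject networks, group
    and union networks, the step-1 and step-2 evidence matrices and BMS
    results, and whether the step-2 winner's A-matrix equals the
    generating one.

    ``subject_cells`` optionally assigns subjects to (age_group,
    propensity) cells; otherwise subjects are split half/half young vs
    older and PPI/PPNI alternating.
    """
    cfg = config or RunConfig()
    net = net or syn.default_source_network()
    if cfg.coupling_scale != 1.0:
        net = syn.GroundTruthNetwork(
            n_nodes=net.n_nodes,
            links=[(s, t, c * cfg.coupling_scale, d) for s, t, c, d in net.links],
            noise_sd=net.noise_sd, self_coefficients=net.self_coefficients,
            node_names=net.node_names)
    n_samples = int(round((cfg.tmax - cfg.tmin) * cfg.sfreq)) + 1
    if subject_cells is None:
        rows = []
        for i in range(n_subjects):
            rows.append({"subject": f"sub{i:03d}",
                         "age_group": "young" if i < n_subjects // 2 else "older",
                         "propensity": "PPI" if i % 2 == 0 else "PPNI"})
        subject_cells = pd.DataFrame(rows)
    seeds = _spawn_seeds(seed, len(subject_cells) * 2 + 4)
    te_window = (cfg.te_window_lo, cfg.te_window_hi)
    dcm_window = (cfg.dcm_window_lo, cfg.dcm_window_hi)
    band = (cfg.band_lo, cfg.band_hi)
    u_range = range(1, cfg.u_max + 1)

    # ---- simulate per-subject source data with condition labels -------
    ensembles: dict[str, TrialEnsemble] = {}
    rng_cond = np.random.default_rng(seeds[-1])
    for si, row in subject_cells.iterrows():
        name = row["subject"]
        p_ill = (illusion_rates or {}).get(name, 0.6)
        conditions = np.where(rng_cond.random(n_trials) < p_ill,
                              "illusion", "no-illusion").tolist()
        mod = (modulation_by_group or {}).get(row["age_group"]) or None
        ensembles[name] = syn.simulate_coupled_network(
            net, n_trials=n_trials, n_samples=n_samples,
            sampling_rate=cfg.sfreq, seed=seeds[si], tmin=cfg.tmin,
            conditions=conditions, modulation=mod, subject=name)

    # ---- TE on odd trials, group networks, union -----------------------
    odd, even = odd_even_split(n_trials)
    subject_nets: dict[str, DirectedNetwork] = {}
    embeddings: dict[str, EmbeddingParams] = {}
    for si, row in subject_cells.iterrows():
        name = row["subject"]
        ens_te = ensembles[name].select_trials(odd).crop(*te_window)
        params = {}
        for ch in ens_te.channel_names:
            params[ch] = te_mod.optimize_embedding(
                ens_te.channel(ch), d_range=range(1, cfg.d_max + 1),
                tau_range=(1,), k_neighbors=cfg.k_ksg, max_points=500,
                tol=cfg.ragwitz_tol)
        embeddings[name] = params
        subject_nets[name] = te_mod.subject_network(
            ens_te, params, u_range=u_range, alpha=cfg.te_alpha,
            n_surrogates=cfg.n_surrogates, k_ksg=cfg.k_ksg,
            stride=cfg.stride, seed=seeds[len(subject_cells) + si])

    cells = subject_cells.set_index("subject")["propensity"]
    nets_ppi = [subject_nets[s] for s in cells.index if cells[s] == "PPI"]
    nets_ppni = [subject_nets[s] for s in cells.index if cells[s] == "PPNI"]
    net_ppi = te_mod.group_network(nets_ppi, cfg.support_fraction)
    net_ppni = te_mod.group_network(nets_ppni, cfg.support_fraction)
    union = te_mod.union_network(net_ppi, net_ppni, "ppi", "ppni")

    result = {
        "ground_truth": net,
        "subject_networks": subject_nets,
        "embeddings": embeddings,
        "net_ppi": net_ppi, "net_ppni": net_ppni, "union": union,
        "subject_cells": subject_cells,
        "winner_matches_truth": False,
        "winning_model": None,
    }
    if union.n_links == 0:
        result["note"] = "empty union network; trivial model space"
        return result

    # ---- step 1: full / single-deletion / PPI-only / PPNI-only --------
    # the single-deletion scan is iterated: as long as removing one more
    # link raises the group evidence, the scan restarts from the pruned
    # model (group TE networks can carry several simultaneous artifacts,
    # e.g. spurious reverse links, which no triangle constraint covers)
    even_ens = [ensembles[s].select_trials(even) for s in subject_cells["subject"]]
    # coupling-sign family first (family-level marginal over the step-1
    # set); BMS then proceeds within the winning family
    models1 = msp.step1_models(union, net_ppi, net_ppni)
    family, family_scores, ev1 = msel.select_family(
        even_ens, models1, band=band, window=dcm_window)
    models1 = [msp.ModelSpec(nodes=list(m.nodes), A=m.A, B=m.B, family=family,
                             provenance=m.provenance, delays=m.delays)
               for m in models1]
    bms1 = msel.rfx_bms(ev1, seed=seeds[-2])
    winner1 = models1[bms1.winner]
    step1_rounds = 1
    while winner1.provenance != "full" and winner1.n_links > 1:
        base = msp.ModelSpec(nodes=winner1.nodes, A=winner1.A, B=winner1.B,
                             family=winner1.family, provenance="full",
                             delays=winner1.delays)
        round_models = [base] + [
            base.without_links([link],
                               provenance=f"single-deletion({link[0]}->{link[1]})")
            for link in sorted(base.links())]
        ev_r = msel.evidence_matrix(even_ens, round_models, band=band,
                                    window=dcm_window)
        bms_r = msel.rfx_bms(ev_r, seed=seeds[-2])
        if round_models[bms_r.winner].provenance == "full":
            winner1 = base
            break
        winner1 = round_models[bms_r.winner]
        step1_rounds += 1
        if step1_rounds > len(models1[0].links()):
            break

    # ---- step 2: triangle-constrained pruning --------------------------
    # triangles are motifs of the full TE union; links already removed by
    # the step-1 winner keep counting against each triangle's budget
    catalog = msp.find_acyclic_triangles(models1[0])
    removed1 = set(models1[0].links()) - set(winner1.links())
    models2 = msp.enumerate_pruned_models(winner1, catalog,
                                          removed_already=removed1)
    if len(models2) > 1:
        ev2 = msel.evidence_matrix(even_ens, models2, band=band, window=dcm_window)
        bms2 = msel.rfx_bms(ev2, seed=seeds[-3])
        winner2 = models2[bms2.winner]
    else:
        ev2, bms2, winner2 = None, None, models2[0]

    truth_A = _truth_adjacency(net, winner2.nodes)
    result.update({
        "family": family, "family_scores": family_scores,
        "models_step1": models1, "evidence_step1": ev1, "bms_step1": bms1,
        "step1_rounds": step1_rounds, "step1_winner": winner1,
        "catalog": catalog,
        "models_step2": models2, "evidence_step2": ev2, "bms_step2": bms2,
        "winning_model": winner2,
        "truth_A": truth_A,
        "winner_matches_truth": bool(np.array_equal(winner2.A, truth_A)),
        "ensembles": ensembles,
        "even_idx": even, "odd_idx": odd,
    })
    return result


def _truth_adjacency(net: syn.GroundTruthNetwork, node_order: list[str]) -> np.ndarray:
    idx = {name: i for i, name in enumerate(node_order)}
    A = np.zeros((len(node_order), len(node_order)), dtype=bool)
    for s, t, *_ in net.links:
        A[idx[net.node_names[s]], idx[net.node_names[t]]] = True
    return A


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full demo study and write outputs plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "outputs": {}}
    seeds = _spawn_seeds(config.seed, 8)
    t_all = time.time()

    # ---- behavior & stratification -------------------------------------
    design = None
    rates_by_subject: dict[str, float] = {}
    if config.run_behavior_stage:
        t0 = time.time()
        spec = syn.PsychometricSpec(
            soas_ms=(100,),
            p_illusion={"young": (config.p_illusion_young,),
                        "older": (config.p_illusion_older,)},
            n_2b1f=60, n_control=30,
            between_subject_sd=config.between_subject_sd)
        table = syn.simulate_behavior(
            spec, {"young": config.n_young, "older": config.n_older},
            seed=seeds[0])
        rates = bhv.illusion_rates(table, per_soa=False)
        strat = bhv.median_split(rates)
        design = strat[["subject", "age_group", "propensity"]]
        rates_by_subject = dict(zip(strat["subject"], strat["rate"]))
        table.to_csv(outdir / "behavior.tsv", sep="\t", index=False)
        strat.to_csv(outdir / "stratification.tsv", sep="\t", index=False)
        manifest["stages"]["behavior"] = {
            "seconds": round(time.time() - t0, 3),
            "n_subjects": len(strat),
            "mean_rate_young": float(strat.loc[strat.age_group == "young", "rate"].mean()),
            "mean_rate_older": float(strat.loc[strat.age_group == "older", "rate"].mean()),
        }

    # ---- time-frequency cluster ANOVA ----------------------------------
    if config.run_tf_stage:
        t0 = time.time()
        effect_sensors = list(range(min(5, config.n_sensors)))
        effects = syn.EffectSpec(
            sensors=effect_sensors,
            multipliers={("young", "PPI"): 1.0, ("young", "PPNI"): 1.0,
                         ("older", "PPI"): config.tf_effect_multiplier,
                         ("older", "PPNI"): config.tf_effect_multiplier})
        ens_tf, tf_design, positions = syn.simulate_tf_experiment(
            effects, n_per_cell=max(config.n_young, config.n_older) // 2,
            n_sensors=config.n_sensors, seed=seeds[1],
            sfreq=config.sfreq, tmin=config.tmin, tmax=config.tmax,
            n_trials=config.tf_n_trials, design=design)
        maps = np.stack([
            tf.band_window_power(
                tf.morlet_tfr(e, freqs=np.arange(8.0, 31.0, 2.0)),
                band=(config.band_lo, config.band_hi),
                window=(config.te_window_lo, config.te_window_hi))
            for e in ens_tf])
        adjacency = tf.build_adjacency(positions, threshold=1.2)
        clusters = tf.cluster_anova_2x2(
            maps, tf_design["age_group"], tf_design["propensity"], adjacency,
            cluster_alpha=config.cluster_alpha, n_perm=config.n_perm,
            seed=seeds[2])
        rows = []
        for eff, res in clusters.items():
            for ci, c in enumerate(res.clusters):
                rows.append({"effect": eff, "cluster": ci, "mass": c["mass"],
                             "p": c["p"],
                             "members": ",".join(map(str, c["members"]))})
        pd.DataFrame(rows, columns=["effect", "cluster", "mass", "p", "members"]
                     ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        manifest["stages"]["timefreq"] = {
            "seconds": round(time.time() - t0, 3),
            "mean_neighbors": adjacency.mean_neighbors,
            "min_p_age": min((c["p"] for c in clusters["A"].clusters),
                             default=1.0),
        }

    # ---- connectivity: TE -> model space -> BMS ------------------------
    if config.run_connectivity_stage:
        t0 = time.time()
        mod_by_group = {
            "young": {},
            "older": {(0, 4): 1.5},   # stronger illusion modulation lBA22->lFFG
        }
        study = run_connectivity_study(
            seed=seeds[3], config=config,
            n_subjects=config.n_young + config.n_older,
            n_trials=config.n_trials,
            subject_cells=design,
            illusion_rates=rates_by_subject or None,
            modulation_by_group=mod_by_group)
        for key in ("net_ppi", "net_ppni", "union"):
            study[key].to_tsv(outdir / f"{key}.tsv")
        study["union"].to_graphml(outdir / "union.graphml")
        conn_info = {
            "seconds": None,
            "n_links_union": study["union"].n_links,
            "winner_matches_truth": study["winner_matches_truth"],
        }
        if study.get("winning_model") is not None:
            (outdir / "winning_model.json").write_text(
                json.dumps(study["winning_model"].to_dict()))

            # step 3: modulation variants + group contrast on even trials
            mods = _modulation_table(study, config)
            if mods is not None:
                mods.to_csv(outdir / "modulations.tsv", sep="\t", index=False)
                contrast = msel.compare_modulations(mods)
                contrast.to_csv(outdir / "modulation_contrast.tsv",
                                sep="\t", index=False)
                conn_info["n_modulated_links"] = int(
                    study["winning_model"].n_links)
            if study.get("evidence_step2") is not None:
                cells = study["subject_cells"]
                young = cells["age_group"].to_numpy() == "young"
                if young.sum() >= 2 and (~young).sum() >= 2:
                    cmp = msel.group_model_comparison(
                        study["evidence_step2"].values[young],
                        study["evidence_step2"].values[~young])
                    conn_info["log_bf_same_vs_diff"] = cmp["log_bf_same_vs_diff"]
        conn_info["seconds"] = round(time.time() - t0, 3)
        manifest["stages"]["connectivity"] = conn_info

    manifest["seconds_total"] = round(time.time() - t_all, 3)
    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                           if p.suffix in (".tsv", ".json", ".graphml")
                           and p.name != "manifest.json"}
    config.to_flat(outdir / "config.txt")
    manifest["outputs"]["config.txt"] = _sha256(outdir / "config.txt")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    return manifest


def _modulation_table(study: dict, config: RunConfig) -> pd.DataFrame | None:
    """Per-subject, per-link illusion-minus-no-illusion coupling change.

    Fits the winning model's couplings separately on illusion and
    no-illusion even trials (counts equalized by seeded stratification)
    and tabulates the difference per link for the age-group contrast.
    """
    winner = study["winning_model"]
    if winner is None or winner.n_links == 0:
        return None
    band = (config.band_lo, config.band_hi)
    window = (config.dcm_window_lo, config.dcm_window_hi)
    rows = []
    for _, srow in study["subject_cells"].iterrows():
        name = srow["subject"]
        ens = study["ensembles"][name].select_trials(study["even_idx"])
        ill = [i for i, c in enumerate(ens.conditions) if c == "illusion"]
        noill = [i for i, c in enumerate(ens.conditions) if c == "no-illusion"]
        if len(ill) < 3 or len(noill) < 3:
            continue
        ill, noill = bhv.stratify_trials(ill, noill, seed=config.seed)
        c_ill = msel.fit_couplings(ens.select_trials(ill), winner, band, window)
        c_no = msel.fit_couplings(ens.select_trials(noill), winner, band, window)
        for link in c_ill:
            rows.append({"subject": name, "group": srow["age_group"],
                         "link": f"{link[0]}->{link[1]}",
                         "modulation": c_ill[link] - c_no[link]})
    if not rows:
        return None
    return pd.DataFrame(rows)
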