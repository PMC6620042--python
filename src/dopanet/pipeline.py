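"""End-to-end orchestration: simulate -> behaviour -> connectivity ->
network detection -> PET kinetics -> group statistics.

`run_analysis` produces a nested report dictionary whose every number is
re-derivable from the stage tables it also returns (and optionally writes);
`check_report` re-derives a core subset from the written stage files and
compares.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import behavioural_summary, penalized_rt
from .community import Partition, consensus_partition, group_consensus, \
    label_networks, zero_negative_weights
from .config import AnalysisConfig, CohortConfig, config_hash
from .connectivity import blockwise_network_strength, condition_connectivity, \
    edge_load_regression, whole_session_connectivity
from .srtm import TAC, BasisSet, FrameSchedule
from .stats import group_strength_test, mediation_bootstrap, meng_compare, \
    one_sample_t, paired_t, rm_anova, spearman_ci, within_subject_regression
from .synthetic import Cohort, FLOAT_FMT, TAC_REGIONS, STRIATUM_WEIGHTS, \
    load_cohort, simulate_cohort

logger = logging.getLogger(__name__)

NETWORKS = ("dmn", "tpn", "between")
BP_REGIONS = ("caudate", "accumbens", "striatum", "snvta")

__all__ = ["run_simulate", "run_analysis", "write_report", "check_report",
           "PipelineError"]


class PipelineError(RuntimeError):
    pass


def _seed_for(master: int, stage: str) -> int:
    tag = zlib.crc32(stage.encode()) % (2 ** 31)
    ss = np.random.SeedSequence([int(master), tag])
    return int(np.random.default_rng(ss).integers(2 ** 31))


def run_simulate(config: CohortConfig, out_dir=None) -> Cohort:
    """Generate a cohort (thin wrapper with stage logging)."""
    logger.info("simulate: n_subjects=%d seed=%d", config.n_subjects,
                config.seed)
    t0 = time.perf_counter()
    cohort = simulate_cohort(config, out_dir=out_dir)
    logger.info("simulate: done in %.1fs", time.perf_counter() - t0)
    return cohort


# ----------------------------------------------------------- stage helpers

def _subject_connectivity(cohort: Cohort, lag: int) -> dict:
    """Per-subject condition-wise z matrices and raw network time courses."""
    z_by_subject = {}
    for sid, sub in cohort.subjects.items():
        try:
            z_by_subject[sid] = {
                load: condition_connectivity(sub.timeseries, load, lag)
                for load in (0, 1, 2)}
        except Exception as exc:
            raise PipelineError(f"connectivity failed for {sid}: {exc}") \
                from exc
    return z_by_subject


def _detect_networks(cohort: Cohort, z_by_subject: dict,
                     acfg: AnalysisConfig) -> dict:
    apriori = cohort.apriori_dmn_mask()
    if acfg.network_detection == "apriori":
        labels = np.where(apriori, 0, 1)
        part = Partition(labels, gamma=acfg.consensus.gamma)
        detect = label_networks(part, apriori)
        detect["method"] = "apriori"
        return detect
    c = acfg.consensus
    seed = _seed_for(acfg.seed, "consensus")
    subject_parts = []
    for i, (sid, zc) in enumerate(z_by_subject.items()):
        w = zero_negative_weights(zc[0].z)
        try:
            subject_parts.append(consensus_partition(
                w, n_iter=c.n_iter, threshold=c.threshold, gamma=c.gamma,
                seed=seed + i, max_rounds=c.max_rounds))
        except Exception as exc:
            raise PipelineError(
                f"subject-level consensus failed for {sid}: {exc}") from exc
    part = group_consensus(subject_parts, n_iter=c.n_iter,
                           threshold=c.threshold, gamma=c.gamma,
                           seed=seed + len(subject_parts),
                           max_rounds=c.max_rounds)
    detect = label_networks(part, apriori)
    detect["method"] = "consensus"
    detect["q"] = part.q
    detect["n_communities"] = part.n_communities
    return detect


def _network_w1_table(cohort: Cohort, z_by_subject: dict,
                      dmn_mask: np.ndarray, lag: int) -> pd.DataFrame:
    rows = []
    for sid in cohort.subject_ids:
        reg = edge_load_regression(z_by_subject[sid], dmn_mask)
        ws = whole_session_connectivity(cohort.subjects[sid].timeseries,
                                        dmn_mask, lag)
        rows.append({
            "subject_id": sid,
            "dmn_w1": reg.dmn_w1, "tpn_w1": reg.tpn_w1,
            "between_w1": reg.between_w1,
            "ws_dmn": ws["dmn"], "ws_tpn": ws["tpn"],
            "ws_between": ws["between"],
        })
    return pd.DataFrame(rows)


def _network_z_by_load(z_by_subject: dict, dmn_mask: np.ndarray,
                       cohort: Cohort) -> pd.DataFrame:
    from .connectivity import edge_masks
    masks = edge_masks(dmn_mask)
    rows = []
    for sid in cohort.subject_ids:
        for load in (0, 1, 2):
            z = z_by_subject[sid][load].z
            rows.append({"subject_id": sid, "load": load,
                         **{net: float(z[m].mean())
                            for net, m in masks.items()}})
    return pd.DataFrame(rows)


def _fit_pet(cohort: Cohort, acfg: AnalysisConfig) -> pd.DataFrame:
    basis = BasisSet(cohort.frame_schedule, acfg.srtm)
    rows = []
    for sid, sub in cohort.subjects.items():
        sched = FrameSchedule(sub.tacs["frame_start_s"].to_numpy(),
                              sub.tacs["frame_dur_s"].to_numpy())
        ref = TAC("reference", sched, sub.tacs["ref_activity"].to_numpy())
        fits = {}
        for region in TAC_REGIONS:
            target = TAC(region, sched, sub.tacs[region].to_numpy())
            try:
                fits[region] = basis.fit(target, ref)
            except Exception as exc:
                raise PipelineError(
                    f"SRTM fit failed for {sid}/{region}: {exc}") from exc
        for region, fit in fits.items():
            rows.append({"subject_id": sid, "region": region,
                         "bp_nd": fit.bp_nd, "r1": fit.r1, "k2": fit.k2,
                         "converged": bool(fit.converged)})
        rows.append({
            "subject_id": sid, "region": "striatum",
            "bp_nd": sum(STRIATUM_WEIGHTS[r] * fits[r].bp_nd
                         for r in STRIATUM_WEIGHTS),
            "r1": np.nan, "k2": np.nan,
            "converged": all(fits[r].converged for r in STRIATUM_WEIGHTS),
        })
    return pd.DataFrame(rows)


def _within_subject(cohort: Cohort, dmn_mask: np.ndarray, lag: int,
                    ratio: float) -> tuple[pd.DataFrame, dict]:
    fits, rows = [], []
    loads_by_block = cohort.schedule.blocks.sort_values("block")[
        "load"].to_numpy(dtype=float)
    for sid, sub in cohort.subjects.items():
        strength = blockwise_network_strength(sub.timeseries, dmn_mask, lag)
        trials = sub.trials
        # block-level pRT with the subject x load baselines
        prt_cells = penalized_rt(trials, ratio).set_index("load")
        baselines = prt_cells["baseline_rt"]
        from .behavior import is_correct
        correct = is_correct(trials)
        block_prt = np.empty(len(loads_by_block))
        for b in range(len(loads_by_block)):
            cell = trials[trials["block"] == b + 1]
            ok = correct.loc[cell.index]
            base = baselines.loc[int(loads_by_block[b])]
            contrib = np.where(ok, cell["rt"].fillna(0.0), ratio * base)
            block_prt[b] = contrib.mean()
        fit = within_subject_regression(block_prt, strength, loads_by_block)
        fits.append(fit)
        rows.append({"subject_id": sid, **dataclasses.asdict(fit)})
    return pd.DataFrame(rows), group_strength_test(fits)


# ------------------------------------------------------------ main analysis

def run_analysis(cohort: Cohort | str | Path,
                 acfg: AnalysisConfig | None = None,
                 out_dir=None) -> dict:
    """Execute the full analysis and return the report dictionary.

    `cohort` may be an in-memory Cohort or a directory written by
    `simulate_cohort`. If `out_dir` is given, stage tables and the report
    (JSON + markdown) are written there.
    """
    acfg = (acfg or AnalysisConfig()).validate()
    if not isinstance(cohort, Cohort):
        cohort = load_cohort(cohort)
    t0 = time.perf_counter()
    lag = acfg.lag_volumes
    ratios = list(acfg.penalization_ratios)
    primary_ratio = ratios[0]

    logger.info("analysis: connectivity stage")
    z_by_subject = _subject_connectivity(cohort, lag)
    logger.info("analysis: network detection (%s)", acfg.network_detection)
    detect = _detect_networks(cohort, z_by_subject, acfg)
    dmn_mask = detect["dmn_mask"]
    net_w1 = _network_w1_table(cohort, z_by_subject, dmn_mask, lag)
    net_z = _network_z_by_load(z_by_subject, dmn_mask, cohort)

    logger.info("analysis: behaviour stage")
    trials = cohort.all_trials()
    behav = behavioural_summary(trials, ratios)
    prt_primary = penalized_rt(trials, primary_ratio)

    logger.info("analysis: PET stage")
    bp = _fit_pet(cohort, acfg)
    bp_wide = bp.pivot(index="subject_id", columns="region",
                       values="bp_nd").loc[cohort.subject_ids]

    logger.info("analysis: within-subject stage")
    within_tab, within_group = _within_subject(cohort, dmn_mask, lag,
                                               primary_ratio)

    logger.info("analysis: group statistics")
    report = {
        "meta": {
            "package_version": __version__,
            "seed": acfg.seed,
            "cohort_seed": cohort.config.seed,
            "config_hash": config_hash(acfg),
            "cohort_config_hash": config_hash(cohort.config),
            "n_subjects": len(cohort.subjects),
            "n_nodes": cohort.config.n_nodes,
            "penalization_ratios": ratios,
        },
        "network_detection": {
            "method": detect["method"],
            "dsc_dmn": detect["dsc_dmn"], "dsc_tpn": detect["dsc_tpn"],
            "n_dmn_nodes": int(dmn_mask.sum()),
            "n_tpn_nodes": int((~dmn_mask).sum()),
        },
    }
    if "q" in detect:
        report["network_detection"]["q"] = detect["q"]
        report["network_detection"]["n_communities"] = detect["n_communities"]

    # ---- group connectivity change
    w1_cols = {net: net_w1[f"{net}_w1"].to_numpy() for net in NETWORKS}
    conn = {f"{net}_w1": one_sample_t(w1_cols[net]).to_dict()
            for net in NETWORKS}
    conn["w1_rm_anova"] = rm_anova(
        np.column_stack([w1_cols[n] for n in NETWORKS])).to_dict()
    conn["w1_pairwise"] = {
        "dmn_vs_tpn": paired_t(w1_cols["dmn"], w1_cols["tpn"]).to_dict(),
        "dmn_vs_between": paired_t(w1_cols["dmn"],
                                   w1_cols["between"]).to_dict(),
        "tpn_vs_between": paired_t(w1_cols["tpn"],
                                   w1_cols["between"]).to_dict(),
    }
    conn["network_z_by_load"] = {
        net: {str(load): float(net_z.loc[net_z["load"] == load, net].mean())
              for load in (0, 1, 2)} for net in NETWORKS}
    report["connectivity"] = conn

    # ---- behaviour
    prt_mat = prt_primary.pivot(index="subject_id", columns="load",
                                values="prt").loc[cohort.subject_ids]
    behav_rep = {
        "prt_by_load": {str(l): float(prt_mat[l].mean()) for l in (0, 1, 2)},
        "prt_rm_anova": rm_anova(prt_mat.to_numpy()).to_dict(),
        "prt_pairwise": {
            "l0_vs_l1": paired_t(prt_mat[0], prt_mat[1]).to_dict(),
            "l1_vs_l2": paired_t(prt_mat[1], prt_mat[2]).to_dict(),
            "l0_vs_l2": paired_t(prt_mat[0], prt_mat[2]).to_dict(),
        },
    }
    robustness = {}
    for ratio in ratios:
        sub = behav[behav["ratio"] == ratio].set_index("subject_id")
        robustness[ratio] = sub.loc[cohort.subject_ids,
                                    "robustness"].to_numpy()
    dp_slope = behav.drop_duplicates("subject_id").set_index("subject_id") \
        .loc[cohort.subject_ids, "dprime_slope"].to_numpy()
    report["behaviour"] = behav_rep

    # ---- correlations
    bp_vec = {r: bp_wide[r].to_numpy() for r in BP_REGIONS}
    corr = {"bp_vs_w1": {}, "bp_vs_ws": {}, "behaviour_vs_w1": {},
            "behaviour_vs_ws": {}, "bp_vs_behaviour": {},
            "dprime_vs_w1": {}}
    for region in BP_REGIONS:
        corr["bp_vs_w1"][region] = {
            net: spearman_ci(bp_vec[region], w1_cols[net]).to_dict()
            for net in NETWORKS}
        corr["bp_vs_ws"][region] = {
            net: spearman_ci(bp_vec[region],
                             net_w1[f"ws_{net}"].to_numpy()).to_dict()
            for net in NETWORKS}
        corr["bp_vs_behaviour"][region] = {
            str(ratio): spearman_ci(bp_vec[region],
                                    robustness[ratio]).to_dict()
            for ratio in ratios}
    for ratio in ratios:
        corr["behaviour_vs_w1"][str(ratio)] = {
            net: spearman_ci(w1_cols[net], robustness[ratio]).to_dict()
            for net in NETWORKS}
    corr["behaviour_vs_ws"][str(primary_ratio)] = {
        net: spearman_ci(net_w1[f"ws_{net}"].to_numpy(),
                         robustness[primary_ratio]).to_dict()
        for net in NETWORKS}
    corr["dprime_vs_w1"] = {
        net: spearman_ci(w1_cols[net], dp_slope).to_dict()
        for net in NETWORKS}

    # ---- Meng comparisons of dependent correlations
    n = len(cohort.subjects)

    def rho(x, y):
        return spearman_ci(x, y).rho

    meng = {
        "caudate_dmn_vs_accumbens_dmn": meng_compare(
            rho(bp_vec["caudate"], w1_cols["dmn"]),
            rho(bp_vec["accumbens"], w1_cols["dmn"]),
            rho(bp_vec["caudate"], bp_vec["accumbens"]), n).to_dict(),
        "caudate_dmn_vs_snvta_dmn": meng_compare(
            rho(bp_vec["caudate"], w1_cols["dmn"]),
            rho(bp_vec["snvta"], w1_cols["dmn"]),
            rho(bp_vec["caudate"], bp_vec["snvta"]), n).to_dict(),
        "caudate_dmn_vs_caudate_tpn": meng_compare(
            rho(bp_vec["caudate"], w1_cols["dmn"]),
            rho(bp_vec["caudate"], w1_cols["tpn"]),
            rho(w1_cols["dmn"], w1_cols["tpn"]), n).to_dict(),
    }
    corr["meng"] = meng
    report["correlations"] = corr

    # ---- mediation: BP (treatment) -> network w1 (mediator) -> robustness
    med_seed = _seed_for(acfg.seed, "mediation")
    mediation = {}
    for i, region in enumerate(BP_REGIONS):
        mediation[region] = {}
        for j, net in enumerate(NETWORKS):
            res = mediation_bootstrap(
                bp_vec[region], w1_cols[net], robustness[primary_ratio],
                n_boot=acfg.n_boot, seed=med_seed + 13 * i + j,
                keep_draws=False)
            mediation[region][net] = res.to_dict()
    report["mediation"] = mediation
    report["within_subject"] = within_group
    report["meta"]["wall_clock_s"] = round(time.perf_counter() - t0, 3)

    stage_tables = {
        "network_w1.tsv": net_w1,
        "network_z_by_load.tsv": net_z,
        "behaviour.tsv": behav,
        "bp_nd.tsv": bp,
        "within_subject.tsv": within_tab,
        "partition.tsv": pd.DataFrame({
            "node_id": cohort.node_labels["node_id"],
            "network_label": detect["network"],
            "apriori_network": cohort.node_labels["apriori_network"],
        }),
    }
    report["_stage_tables"] = stage_tables
    if out_dir is not None:
        write_report(report, out_dir)
    return report


# ----------------------------------------------------------------- reports

def _strip_private(report: dict) -> dict:
    return {k: v for k, v in report.items() if not k.startswith("_")}


def write_report(report: dict, out_dir, formats=("json", "markdown")) -> list:
    """Write stage tables plus report.json / report.md.

    The markdown report embeds the full JSON payload in a fenced block, so
    converting back to JSON is lossless.
    """
    public = _strip_private(report)
    if not public.get("meta"):
        raise PipelineError("refusing to write an empty report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in report.get("_stage_tables", {}).items():
        # full precision so the checker can re-derive statistics exactly
        table.to_csv(out / name, sep="\t", index=False,
                     float_format="%.12g")
        written.append(out / name)
    payload = json.dumps(public, indent=2, sort_keys=True, default=float)
    if "json" in formats:
        (out / "report.json").write_text(payload + "\n")
        written.append(out / "report.json")
    if "markdown" in formats:
        md = _markdown_report(public, payload)
        (out / "report.md").write_text(md)
        written.append(out / "report.md")
    return written


def _markdown_report(public: dict, payload: str) -> str:
    meta = public["meta"]
    lines = [
        "# Analysis report",
        "",
        f"- package version: {meta['package_version']}",
        f"- analysis seed: {meta['seed']} | cohort seed: "
        f"{meta['cohort_seed']}",
        f"- config hash: {meta['config_hash']} | cohort config hash: "
        f"{meta['cohort_config_hash']}",
        f"- subjects: {meta['n_subjects']}, nodes: {meta['n_nodes']}",
        "",
        "## Headline statistics",
        "",
    ]
    conn = public["connectivity"]
    for net in NETWORKS:
        e = conn[f"{net}_w1"]
        lines.append(f"- group mean {net.upper()} w1 = {e['mean']:.4f} "
                     f"(t_{e['df']} = {e['t']:.2f}, p = {e['p']:.3g})")
    c = public["correlations"]["bp_vs_w1"]["caudate"]["dmn"]
    lines.append(f"- Spearman rho(caudate BP_ND, DMN w1) = {c['rho']:.3f} "
                 f"[{c['ci_low']:.2f}, {c['ci_high']:.2f}], "
                 f"p = {c['p']:.3g}")
    ratio = str(meta["penalization_ratios"][0])
    b = public["correlations"]["behaviour_vs_w1"][ratio]["dmn"]
    lines.append(f"- Spearman rho(DMN w1, -dpRT({ratio})) = {b['rho']:.3f} "
                 f"[{b['ci_low']:.2f}, {b['ci_high']:.2f}], "
                 f"p = {b['p']:.3g}")
    m = public["mediation"]["caudate"]["dmn"]["acme"]
    lines.append(f"- ACME (caudate BP -> DMN w1 -> -dpRT) = {m['est']:.4f} "
                 f"[{m['ci_low']:.3f}, {m['ci_high']:.3f}], "
                 f"p = {m['p']:.3g}")
    lines += ["", "## Full payload", "", "```json", payload, "```", ""]
    return "\n".join(lines)


def report_to_json(markdown_text: str) -> dict:
    """Recover the JSON payload embedded in a markdown report."""
    try:
        block = markdown_text.split("```json\n", 1)[1].rsplit("\n```", 1)[0]
    except IndexError as exc:
        raise PipelineError("markdown report has no JSON payload") from exc
    return json.loads(block)


# ------------------------------------------------------------------- check

def check_report(report_dir, atol: float = 1e-8) -> list[str]:
    """Recompute core group statistics from the stage tables and compare
    with report.json; returns a list of mismatch descriptions (empty = OK).
    """
    out = Path(report_dir)
    report = json.loads((out / "report.json").read_text())
    net_w1 = pd.read_csv(out / "network_w1.tsv", sep="\t")
    behav = pd.read_csv(out / "behaviour.tsv", sep="\t")
    bp = pd.read_csv(out / "bp_nd.tsv", sep="\t")
    problems = []

    def close(a, b, what):
        if not np.isclose(a, b, atol=atol, rtol=1e-6, equal_nan=True):
            problems.append(f"{what}: report {a!r} vs recomputed {b!r}")

    for net in NETWORKS:
        got = report["connectivity"][f"{net}_w1"]
        recomputed = one_sample_t(net_w1[f"{net}_w1"]).to_dict()
        for key in ("t", "p", "mean"):
            close(got[key], recomputed[key], f"{net}_w1.{key}")

    ratio = report["meta"]["penalization_ratios"][0]
    rb = behav[behav["ratio"] == ratio].set_index("subject_id")
    order = net_w1["subject_id"]
    robustness = rb.loc[order, "robustness"].to_numpy()
    bp_wide = bp.pivot(index="subject_id", columns="region",
                       values="bp_nd").loc[order]
    got = report["correlations"]["bp_vs_w1"]["caudate"]["dmn"]
    rec = spearman_ci(bp_wide["caudate"].to_numpy(),
                      net_w1["dmn_w1"].to_numpy()).to_dict()
    for key in ("rho", "p"):
        close(got[key], rec[key], f"bp_vs_w1.caudate.dmn.{key}")
    got = report["correlations"]["behaviour_vs_w1"][str(ratio)]["dmn"]
    rec = spearman_ci(net_w1["dmn_w1"].to_numpy(), robustness).to_dict()
    for key in ("rho", "p"):
        close(got[key], rec[key], f"behaviour_vs_w1.dmn.{key}")

    # mediation point estimate (bootstrap intervals are seed-dependent)
    from .stats import _ols_paths
    a, b, _ = _ols_paths(bp_wide["caudate"].to_numpy(),
                         net_w1["dmn_w1"].to_numpy(), robustness)
    close(report["mediation"]["caudate"]["dmn"]["acme"]["est"], a * b,
          "mediation.caudate.dmn.acme.est")
    return problems
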