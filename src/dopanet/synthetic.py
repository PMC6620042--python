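"""Synthetic PET/fMRI working-memory cohort with planted effect structure.

Generates, per subject: an n-back trial table, parcellated BOLD node time
series whose condition-dependent correlation structure carries a planted
linear load effect on the Fisher-z scale, and SRTM-generated striatal
time-activity curves. Subject-level latents (binding potentials, true
connectivity slopes, behavioural robustness) are recorded so that every
downstream estimate can be checked against its ground truth.

Planted structure
-----------------
* within-DMN correlation at load L: tanh(atanh(base_corr_dmn) + slope_s*L
  + eta_b), where slope_s is the subject's true DMN slope and eta_b a
  block-specific fluctuation; within-TPN analogous; rest volumes use the
  load-0 structure without fluctuation.
* bp_caudate and slope_s are coupled through a Gaussian copula so their
  Spearman correlation targets rho_bp_slope (positive BP -> less negative
  slope).
* behavioural robustness (-dpRT) is planted as
  behav_slope_coupling * slope_s + direct_bp_behaviour * bp + noise and
  enters trial generation through the per-load mean RT; block-level RT is
  additionally coupled to eta_b so block-wise DMN strength predicts
  block-wise performance within subject.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CohortConfig, ConfigurationError, config_hash
from .connectivity import REST, ParcelTimeSeries
from .srtm import FrameSchedule, frame_average, reference_curve, \
    srtm_forward_fine

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"
RT_SD = 0.12
RT_MIN, RT_MAX = 0.2, 2.0
TAC_REGIONS = ("caudate", "putamen", "accumbens", "snvta")
STRIATUM_WEIGHTS = {"caudate": 0.40, "putamen": 0.45, "accumbens": 0.15}

__all__ = [
    "BlockSchedule", "SubjectLatents", "Cohort", "GenerationError",
    "make_block_schedule", "draw_latents", "simulate_trials",
    "simulate_bold", "simulate_tacs", "simulate_cohort", "load_cohort",
    "default_node_labels",
]


class GenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------- schedule

@dataclass
class BlockSchedule:
    """Pseudo-randomised block order with onsets (seconds)."""

    blocks: pd.DataFrame   # columns: block, load, onset_s, duration_s

    def __post_init__(self):
        b = self.blocks
        loads, counts = np.unique(b["load"], return_counts=True)
        if set(loads) != {0, 1, 2} or len(set(counts)) != 1:
            raise ConfigurationError(
                "schedule must contain an equal number of 0/1/2-back blocks")
        ends = b["onset_s"] + b["duration_s"]
        if (b["onset_s"].to_numpy()[1:] < ends.to_numpy()[:-1]).any():
            raise ConfigurationError("blocks overlap")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def volume_labels(self, tr: float, n_volumes: int,
                      delay_s: float = 0.0) -> np.ndarray:
        """Condition per volume (REST = -1); the block covering a volume is
        judged at the volume midpoint, optionally delayed."""
        labels = np.full(n_volumes, REST, dtype=np.int64)
        mids = (np.arange(n_volumes) + 0.5) * tr - delay_s
        for _, row in self.blocks.iterrows():
            inside = (mids >= row["onset_s"]) & \
                     (mids < row["onset_s"] + row["duration_s"])
            labels[inside] = int(row["load"])
        return labels

    def volume_block_index(self, tr: float, n_volumes: int,
                           delay_s: float = 0.0) -> np.ndarray:
        """Block index per volume (-1 outside any block)."""
        idx = np.full(n_volumes, -1, dtype=np.int64)
        mids = (np.arange(n_volumes) + 0.5) * tr - delay_s
        for _, row in self.blocks.iterrows():
            inside = (mids >= row["onset_s"]) & \
                     (mids < row["onset_s"] + row["duration_s"])
            idx[inside] = int(row["block"]) - 1
        return idx


def make_block_schedule(config: CohortConfig, seed: int) -> BlockSchedule:
    """Permute blocks_per_load copies of each load over the session.

    Each task block is followed by a rest period of rest_len seconds;
    raises if the schedule does not fit in n_volumes * tr.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    loads = np.repeat([0, 1, 2], config.blocks_per_load)
    loads = rng.permutation(loads)
    onsets = np.arange(config.n_blocks) * (config.block_len + config.rest_len)
    blocks = pd.DataFrame({
        "block": np.arange(1, config.n_blocks + 1),
        "load": loads,
        "onset_s": onsets,
        "duration_s": np.full(config.n_blocks, config.block_len),
    })
    total = config.n_blocks * (config.block_len + config.rest_len)
    if total > config.session_length_s:
        raise ConfigurationError(
            f"schedule of {total:.0f}s exceeds session "
            f"{config.session_length_s:.0f}s")
    return BlockSchedule(blocks)


# ----------------------------------------------------------------- latents

def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _orthogonalized(noise: np.ndarray, *others: np.ndarray) -> np.ndarray:
    """Residualise `noise` against the given regressors and standardise."""
    x = np.column_stack([np.ones_like(noise), *others])
    resid = noise - x @ np.linalg.lstsq(x, noise, rcond=None)[0]
    return _standardize(resid)


def _sample_spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = np.argsort(np.argsort(x)).astype(float)
    ry = np.argsort(np.argsort(y)).astype(float)
    return float(np.corrcoef(rx, ry)[0, 1])


def _rank_calibrated(anchor: np.ndarray, noise: np.ndarray,
                     rho_target: float, tol: float = 1e-3) -> np.ndarray:
    """A vector whose sample Spearman correlation with `anchor` hits the
    target, built as lam*anchor + sqrt(1-lam^2)*orthogonal noise with the
    mixing weight found by bisection."""
    a = _standardize(anchor)
    e = _orthogonalized(noise, a)

    def mix(lam):
        return lam * a + np.sqrt(max(0.0, 1.0 - lam ** 2)) * e

    if abs(rho_target) < tol:
        return e
    # Spearman(mix(lam), anchor) is monotone increasing in lam
    lo, hi = -1.0, 1.0
    lam = 2.0 * np.sin(np.pi * rho_target / 6.0)
    for _ in range(60):
        r = _sample_spearman(a, mix(lam))
        if abs(r - rho_target) < tol:
            break
        if r < rho_target:
            lo = lam
        else:
            hi = lam
        lam = 0.5 * (lo + hi)
    return mix(lam)


@dataclass
class SubjectLatents:
    """Ground-truth record for one synthetic subject."""

    subject_id: str
    bp_caudate: float
    bp_putamen: float
    bp_accumbens: float
    bp_striatum: float
    bp_snvta: float
    dmn_slope_true: float
    tpn_slope_true: float
    robustness_true: float     # planted -dpRT, seconds per load level
    ability: float             # standardised robustness, drives error rates
    rt_intercept: float        # mean correct RT at load 0, seconds
    base_z_dmn_offset: float   # stable subject offset of within-DMN z
    base_z_tpn_offset: float   # stable subject offset of within-TPN z
    ref_amplitude: float       # reference TAC peak, arbitrary kBq/mL
    block_dmn_offsets: np.ndarray  # eta_b, Fisher-z units, length n_blocks

    def __post_init__(self):
        if min(self.bp_caudate, self.bp_putamen, self.bp_accumbens,
               self.bp_striatum, self.bp_snvta) < 0:
            raise GenerationError("BP_ND values must be non-negative")
        if not np.isfinite(self.dmn_slope_true):
            raise GenerationError("dmn_slope_true must be finite")


def draw_latents(config: CohortConfig, seed: int,
                 block_loads: np.ndarray | None = None
                 ) -> list[SubjectLatents]:
    """Draw subject latents with the Gaussian-copula BP <-> slope coupling.

    The Pearson correlation of the underlying normals is 2*sin(pi*rho/6),
    the exact value whose bivariate-normal Spearman correlation equals the
    requested rho_bp_slope (both margins are monotone in their normal).

    Block-level DMN fluctuations eta_b are defined as deviations around the
    condition mean: when `block_loads` is given they are centred within each
    load, so they perturb individual blocks without disturbing the planted
    per-condition connectivity (and hence the load slope).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_subjects

    z1 = rng.standard_normal(n)
    bp_caud = config.bp_mean + config.bp_sd * z1
    for _ in range(100):
        bad = bp_caud <= 0
        if not bad.any():
            break
        bp_caud[bad] = config.bp_mean + \
            config.bp_sd * rng.standard_normal(int(bad.sum()))
        z1[bad] = (bp_caud[bad] - config.bp_mean) / config.bp_sd
    else:
        raise GenerationError("could not draw non-negative caudate BP_ND")

    # plant the rank coupling at the *sample* level: mix an independent
    # standardised component into z1 and bisect the mixing weight until the
    # realised Spearman correlation equals the target (the copula value
    # 2*sin(pi*rho/6) seeds the search)
    z2 = _rank_calibrated(z1, rng.standard_normal(n), config.rho_bp_slope)
    dmn_slope = config.mean_dmn_slope + \
        config.sd_dmn_slope * _standardize(z2)
    tpn_slope = config.mean_tpn_slope + \
        config.sd_dmn_slope * _standardize(rng.standard_normal(n))

    # other regions: putamen/accumbens share variance with the caudate,
    # SN/VTA is independent (it serves as the null control region)
    e_put = rng.standard_normal(n)
    e_acc = rng.standard_normal(n)
    bp_put = np.clip(2.6 + 0.40 * (0.7 * z1 + np.sqrt(0.51) * e_put), 0.05,
                     None)
    bp_acc = np.clip(3.4 + 0.50 * (0.5 * z1 + np.sqrt(0.75) * e_acc), 0.05,
                     None)
    bp_sn = np.clip(0.7 + 0.15 * rng.standard_normal(n), 0.05, None)
    bp_str = (STRIATUM_WEIGHTS["caudate"] * bp_caud +
              STRIATUM_WEIGHTS["putamen"] * bp_put +
              STRIATUM_WEIGHTS["accumbens"] * bp_acc)

    behav_noise = _orthogonalized(rng.standard_normal(n), dmn_slope, bp_caud)
    robustness = (config.behav_slope_coupling * dmn_slope +
                  config.direct_bp_behaviour * bp_caud +
                  config.behav_noise_sd * behav_noise)
    centre = (config.behav_slope_coupling * config.mean_dmn_slope +
              config.direct_bp_behaviour * config.bp_mean)
    scale = np.sqrt((config.behav_slope_coupling * config.sd_dmn_slope) ** 2 +
                    (config.direct_bp_behaviour * config.bp_sd) ** 2 +
                    config.behav_noise_sd ** 2)
    ability = (robustness - centre) / scale if scale > 0 else \
        np.zeros(n)

    rt0 = np.clip(0.55 + 0.03 * rng.standard_normal(n), 0.45, 0.70)
    base_dmn_off = config.subject_base_z_sd * rng.standard_normal(n)
    base_tpn_off = config.subject_base_z_sd * rng.standard_normal(n)
    ref_amp = 25.0 * (1.0 + 0.10 * rng.standard_normal(n))
    etas = config.dmn_block_jitter_sd * \
        rng.standard_normal((n, config.n_blocks))
    if block_loads is not None:
        block_loads = np.asarray(block_loads)
        for load in np.unique(block_loads):
            sel = block_loads == load
            etas[:, sel] -= etas[:, sel].mean(axis=1, keepdims=True)

    width = max(2, len(str(n)))
    return [
        SubjectLatents(
            subject_id=f"sub-{i + 1:0{width}d}",
            bp_caudate=float(bp_caud[i]), bp_putamen=float(bp_put[i]),
            bp_accumbens=float(bp_acc[i]), bp_striatum=float(bp_str[i]),
            bp_snvta=float(bp_sn[i]),
            dmn_slope_true=float(dmn_slope[i]),
            tpn_slope_true=float(tpn_slope[i]),
            robustness_true=float(robustness[i]),
            ability=float(ability[i]),
            rt_intercept=float(rt0[i]),
            base_z_dmn_offset=float(base_dmn_off[i]),
            base_z_tpn_offset=float(base_tpn_off[i]),
            ref_amplitude=float(abs(ref_amp[i])),
            block_dmn_offsets=etas[i].copy(),
        )
        for i in range(n)
    ]


# ------------------------------------------------------------------ trials

def simulate_trials(latents: SubjectLatents, schedule: BlockSchedule,
                    config: CohortConfig, seed: int,
                    base_wrong: float = 0.015, base_omit: float = 0.010,
                    load_wrong: float = 0.020,
                    load_omit: float = 0.012) -> pd.DataFrame:
    """Trial table for one subject.

    Mean RT rises with load by the subject's planted pRT slope
    (-robustness) plus the block-level DMN-strength coupling; wrong-key and
    omission probabilities rise with load and fall with ability.
    Columns: subject_id, block, load, trial, target, response, rt.
    """
    rng = np.random.default_rng(seed)
    delta_prt = -latents.robustness_true
    ability_factor = float(np.exp(-0.4 * latents.ability))
    rows = []
    for _, blk in schedule.blocks.iterrows():
        b = int(blk["block"]) - 1
        load = int(blk["load"])
        eta = float(latents.block_dmn_offsets[b])
        rt_mean = (latents.rt_intercept + delta_prt * load +
                   config.block_strength_coupling * eta)
        p_wrong = np.clip((base_wrong + load_wrong * load) * ability_factor,
                          0.0, 0.45)
        p_omit = np.clip((base_omit + load_omit * load) * ability_factor,
                         0.0, 0.45)
        for trial in range(1, config.trials_per_block + 1):
            target = bool(rng.random() < config.target_rate)
            u = rng.random()
            if u < p_omit:
                response, rt = "omitted", np.nan
            else:
                rt = float(np.clip(rng.normal(rt_mean, RT_SD),
                                   RT_MIN, RT_MAX))
                if u < p_omit + p_wrong:
                    response = "non-target" if target else "target"
                else:
                    response = "target" if target else "non-target"
            rows.append({
                "subject_id": latents.subject_id, "block": b + 1,
                "load": load, "trial": trial, "target": int(target),
                "response": response, "rt": rt,
            })
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- BOLD

def _network_correlation(config: CohortConfig, z_dmn: float, z_tpn: float,
                         ) -> np.ndarray:
    n, nd = config.n_nodes, config.n_dmn_nodes
    r = np.full((n, n), config.base_corr_between)
    r[:nd, :nd] = np.tanh(z_dmn)
    r[nd:, nd:] = np.tanh(z_tpn)
    np.fill_diagonal(r, 1.0)
    return r


def _nearest_pd(corr: np.ndarray) -> tuple[np.ndarray, bool]:
    """Eigenvalue-clipped, diagonal-renormalised repair of a correlation."""
    vals = np.linalg.eigvalsh(corr)
    if vals.min() > 1e-10:
        return corr, False
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 1e-6, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    if np.linalg.eigvalsh(fixed).min() <= 0:
        raise GenerationError(
            "target covariance not positive definite even after repair")
    return fixed, True


def simulate_bold(latents: SubjectLatents, schedule: BlockSchedule,
                  config: CohortConfig, seed: int) -> ParcelTimeSeries:
    """Parcellated BOLD time series with condition-switched covariance.

    Each volume is drawn from a zero-mean multivariate normal whose
    correlation structure reflects the task condition active one
    haemodynamic delay earlier; iid Gaussian noise of sd `noise_sd` is
    added on top of the unit-variance network signal. The stored labels
    are acquisition-aligned (undelayed).
    """
    rng = np.random.default_rng(seed)
    n_vol, n_nodes = config.n_volumes, config.n_nodes
    block_idx = schedule.volume_block_index(
        config.tr, n_vol, delay_s=config.hemodynamic_delay_s)

    z_dmn0 = np.arctanh(config.base_corr_dmn) + latents.base_z_dmn_offset
    z_tpn0 = np.arctanh(config.base_corr_tpn) + latents.base_z_tpn_offset

    raw = rng.standard_normal((n_vol, n_nodes))
    data = np.empty((n_vol, n_nodes))
    repaired = False

    rest = block_idx < 0
    rest_corr, rep = _nearest_pd(_network_correlation(config, z_dmn0, z_tpn0))
    repaired |= rep
    chol = np.linalg.cholesky(rest_corr)
    data[rest] = raw[rest] @ chol.T

    loads = dict(zip(schedule.blocks["block"] - 1, schedule.blocks["load"]))
    for b in np.unique(block_idx[block_idx >= 0]):
        load = int(loads[int(b)])
        z_dmn = z_dmn0 + latents.dmn_slope_true * load + \
            float(latents.block_dmn_offsets[int(b)])
        z_tpn = z_tpn0 + latents.tpn_slope_true * load
        corr, rep = _nearest_pd(_network_correlation(config, z_dmn, z_tpn))
        repaired |= rep
        chol = np.linalg.cholesky(corr)
        sel = block_idx == b
        data[sel] = raw[sel] @ chol.T

    if repaired:
        logger.warning("%s: correlation target required positive-definite "
                       "repair", latents.subject_id)
    if config.noise_sd > 0:
        data = data + config.noise_sd * rng.standard_normal(data.shape)

    node_ids = default_node_labels(config)["node_id"].tolist()
    labels = schedule.volume_labels(config.tr, n_vol, delay_s=0.0)
    return ParcelTimeSeries(data=data.T, node_ids=node_ids, labels=labels,
                            tr=config.tr)


# --------------------------------------------------------------------- TAC

def simulate_tacs(latents: SubjectLatents, config: CohortConfig, seed: int,
                  schedule: FrameSchedule | None = None) -> pd.DataFrame:
    """SRTM forward-model TACs (frame-averaged) for the striatal regions.

    Noise is Gaussian per frame with variance inversely proportional to
    frame duration (sd scaled to `tac_noise_frac` of the curve peak for a
    60 s frame).
    """
    schedule = schedule or FrameSchedule.default_31()
    rng = np.random.default_rng(seed)
    dt = 1.0
    t = np.arange(0.0, schedule.end_time + dt / 2, dt)
    ref_fine = reference_curve(t, amplitude=latents.ref_amplitude)
    ref_frames = frame_average(ref_fine, t, schedule)

    def noisy(frames):
        peak = np.max(np.abs(frames))
        sd = config.tac_noise_frac * peak * np.sqrt(60.0 / schedule.dur)
        return frames + rng.standard_normal(len(frames)) * sd

    bp_by_region = {
        "caudate": latents.bp_caudate, "putamen": latents.bp_putamen,
        "accumbens": latents.bp_accumbens, "snvta": latents.bp_snvta,
    }
    out = {
        "frame_start_s": schedule.start,
        "frame_dur_s": schedule.dur,
        "ref_activity": noisy(ref_frames),
    }
    for region in TAC_REGIONS:
        r1 = float(np.clip(rng.normal(0.90, 0.05), 0.7, 1.1))
        k2 = float(np.clip(rng.normal(0.35, 0.04), 0.2, 0.5))
        fine = srtm_forward_fine(ref_fine, t, r1, k2, bp_by_region[region])
        out[region] = noisy(frame_average(fine, t, schedule))
    return pd.DataFrame(out)


# ------------------------------------------------------------------ cohort

def default_node_labels(config: CohortConfig) -> pd.DataFrame:
    """A-priori node -> network table: DMN first, then alternating DAN/FPN."""
    n, nd = config.n_nodes, config.n_dmn_nodes
    width = len(str(n - 1))
    ids = [f"node{i:0{width}d}" for i in range(n)]
    networks = ["DMN"] * nd + \
        [("DAN" if i % 2 == 0 else "FPN") for i in range(n - nd)]
    return pd.DataFrame({"node_id": ids, "apriori_network": networks})


@dataclass
class SubjectData:
    latents: SubjectLatents
    trials: pd.DataFrame
    timeseries: ParcelTimeSeries
    tacs: pd.DataFrame


@dataclass
class Cohort:
    """In-memory cohort bundle (see `simulate_cohort` / `load_cohort`)."""

    config: CohortConfig
    schedule: BlockSchedule
    node_labels: pd.DataFrame
    subjects: dict[str, SubjectData]
    frame_schedule: FrameSchedule

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects)

    def latents_frame(self) -> pd.DataFrame:
        rows = []
        for sid, sub in self.subjects.items():
            lat = dataclasses.asdict(sub.latents)
            etas = lat.pop("block_dmn_offsets")
            for b, e in enumerate(etas):
                lat[f"eta_block{b + 1:02d}"] = float(e)
            rows.append(lat)
        return pd.DataFrame(rows)

    def all_trials(self) -> pd.DataFrame:
        return pd.concat([s.trials for s in self.subjects.values()],
                         ignore_index=True)

    def apriori_dmn_mask(self) -> np.ndarray:
        return (self.node_labels["apriori_network"] == "DMN").to_numpy()

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        kw = dict(sep="\t", index=False, float_format=FLOAT_FMT)
        self.schedule.blocks.to_csv(out / "schedule.tsv", **kw)
        self.node_labels.to_csv(out / "node_labels.tsv", **kw)
        self.latents_frame().to_csv(out / "latents.tsv", **kw)
        for sid, sub in self.subjects.items():
            sdir = out / sid
            sdir.mkdir(exist_ok=True)
            sub.timeseries.to_frame().to_csv(sdir / "timeseries.tsv", **kw)
            sub.trials.to_csv(sdir / "trials.tsv", **kw)
            sub.tacs.to_csv(sdir / "tacs.tsv", **kw)
        manifest = {
            "config": dataclasses.asdict(self.config),
            "config_hash": config_hash(self.config),
            "seed": self.config.seed,
            "n_subjects": len(self.subjects),
            "subjects": self.subject_ids,
            "files": ["schedule.tsv", "node_labels.tsv", "latents.tsv"] +
                     [f"{sid}/{name}" for sid in self.subject_ids
                      for name in ("timeseries.tsv", "trials.tsv",
                                   "tacs.tsv")],
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return out


def simulate_cohort(config: CohortConfig, out_dir=None) -> Cohort:
    """Generate a full cohort; optionally write the on-disk layout."""
    config.validate()
    master = np.random.default_rng(config.seed)
    schedule_seed, latents_seed = master.integers(2 ** 31, size=2)
    schedule = make_block_schedule(config, int(schedule_seed))
    block_loads = schedule.blocks.sort_values("block")["load"].to_numpy()
    latents = draw_latents(config, int(latents_seed), block_loads=block_loads)
    sub_seeds = master.integers(2 ** 31, size=(config.n_subjects, 3))

    subjects = {}
    frame_schedule = FrameSchedule.default_31()
    for i, lat in enumerate(latents):
        trials = simulate_trials(lat, schedule, config, int(sub_seeds[i, 0]))
        ts = simulate_bold(lat, schedule, config, int(sub_seeds[i, 1]))
        tacs = simulate_tacs(lat, config, int(sub_seeds[i, 2]),
                             frame_schedule)
        subjects[lat.subject_id] = SubjectData(
            latents=lat, trials=trials, timeseries=ts, tacs=tacs)

    cohort = Cohort(config=config, schedule=schedule,
                    node_labels=default_node_labels(config),
                    subjects=subjects, frame_schedule=frame_schedule)
    if out_dir is not None:
        try:
            cohort.write(out_dir)
        except OSError as exc:
            raise GenerationError(
                f"failed writing cohort to {out_dir}: {exc}") from exc
    return cohort


def load_cohort(cohort_dir) -> Cohort:
    """Reload a cohort written by `Cohort.write` (latents included)."""
    root = Path(cohort_dir)
    try:
        manifest = json.loads((root / "manifest.json").read_text())
    except OSError as exc:
        raise GenerationError(f"cannot read manifest in {root}: {exc}") from exc
    cfg_dict = manifest["config"]
    config = CohortConfig(**cfg_dict)
    schedule = BlockSchedule(pd.read_csv(root / "schedule.tsv", sep="\t"))
    node_labels = pd.read_csv(root / "node_labels.tsv", sep="\t")
    latents_df = pd.read_csv(root / "latents.tsv", sep="\t")
    eta_cols = sorted(c for c in latents_df.columns
                      if c.startswith("eta_block"))
    frame_schedule = FrameSchedule.default_31()
    labels = schedule.volume_labels(config.tr, config.n_volumes, delay_s=0.0)

    subjects = {}
    for _, row in latents_df.iterrows():
        sid = row["subject_id"]
        lat = SubjectLatents(
            subject_id=sid,
            bp_caudate=row["bp_caudate"], bp_putamen=row["bp_putamen"],
            bp_accumbens=row["bp_accumbens"],
            bp_striatum=row["bp_striatum"], bp_snvta=row["bp_snvta"],
            dmn_slope_true=row["dmn_slope_true"],
            tpn_slope_true=row["tpn_slope_true"],
            robustness_true=row["robustness_true"],
            ability=row["ability"], rt_intercept=row["rt_intercept"],
            base_z_dmn_offset=row["base_z_dmn_offset"],
            base_z_tpn_offset=row["base_z_tpn_offset"],
            ref_amplitude=row["ref_amplitude"],
            block_dmn_offsets=row[eta_cols].to_numpy(dtype=float),
        )
        sdir = root / sid
        ts_frame = pd.read_csv(sdir / "timeseries.tsv", sep="\t")
        ts = ParcelTimeSeries(data=ts_frame.to_numpy().T,
                              node_ids=list(ts_frame.columns),
                              labels=labels, tr=config.tr)
        trials = pd.read_csv(sdir / "trials.tsv", sep="\t")
        tacs = pd.read_csv(sdir / "tacs.tsv", sep="\t")
        subjects[sid] = SubjectData(latents=lat, trials=trials,
                                    timeseries=ts, tacs=tacs)
    return Cohort(config=config, schedule=schedule, node_labels=node_labels,
                  subjects=subjects, frame_schedule=frame_schedule)
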