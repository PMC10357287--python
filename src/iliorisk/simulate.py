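"""Synthetic iliofemoral vessels, plaques and patient cohorts.

No patient CT data ship with this package; this module generates
geometry and cohorts with the statistical structure reported for
transfemoral-TAVR populations so that every measurement and modelling
routine can be exercised end to end:

* vessels are 3D polylines built from straight runs joined by planar
  circular elbows (elbow planes rotated randomly about the vessel axis),
  ~205 mm ideal length with about 3 curves for normal anatomy and more,
  sharper curves with a smaller minimal lumen diameter for high-risk
  anatomy;
* a stenotic dip planted exactly on a grid point fixes the minimal
  lumen diameter (MLD);
* outcomes are Bernoulli draws from a logistic mechanism on the
  *extracted* features (SOA, NOC, MLD, SFAR > 1, calcification ≥ III) —
  extracted by running the measurement pipeline on the generated
  geometry, never copied from the latent draws — with the intercept
  calibrated so the cohort incidence matches a target (default 7.2%).

Reproducibility: one global seed; patient ``i`` uses the independent
substream ``SeedSequence(seed, spawn_key=(STREAM_PATIENT, i))`` so any
patient regenerates bit-exactly in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .centerline_geometry import (BIFURCATION, PUNCTURE, Centerline, analyze)
from .errors import InvalidInputError
from .plaque import Plaque, PlaquePosition
from .risk_score import sfar as sfar_ratio

STREAM_PATIENT = 1
STREAM_CALIBRATION = 2

#: Matched-cohort distribution of complication types.
IVC_TYPES = ("dissection", "perforation", "pseudoaneurysm",
             "stenosis_thrombosis_embolism_ischemia", "av_fistula")
IVC_TYPE_PROBS = (0.360, 0.250, 0.198, 0.163, 0.029)


@dataclass(frozen=True)
class StratumParams:
    """Vessel-anatomy distribution for one latent stratum."""

    noc_poisson_mean: float  # NOC = 2 + Poisson(mean)
    angle_mean: float  # per-curve turn angle mean, degrees
    angle_shape: float  # Gamma shape for per-curve angles
    mld_mean: float  # mm
    mld_sd: float  # mm
    p_plaque: float  # probability of carrying a calcified plaque
    p_cat3_given_plaque: float  # P(lumen fraction ≥ 0.5 | plaque)


#: Normal anatomy: ~3.4 curves of ~32° (SOA ≈ 110), MLD 6.8 mm.
CONTROL_STRATUM = StratumParams(noc_poisson_mean=1.4, angle_mean=110 / 3.4,
                                angle_shape=16.0, mld_mean=6.8, mld_sd=1.0,
                                p_plaque=0.7, p_cat3_given_plaque=0.31)
#: High-risk anatomy: ~5.6 curves of ~29° (SOA ≈ 165), MLD 5.6 mm.
HIGH_RISK_STRATUM = StratumParams(noc_poisson_mean=3.6,
                                  angle_mean=165 / 5.6, angle_shape=16.0,
                                  mld_mean=5.6, mld_sd=0.8,
                                  p_plaque=0.7, p_cat3_given_plaque=0.48)


@dataclass(frozen=True)
class OutcomeBetas:
    """Log-odds coefficients of the outcome mechanism (directions follow
    the multivariable associations: tortuosity and calcification raise
    risk, lumen size lowers it; magnitudes are generator configuration,
    not clinical claims)."""

    soa: float = 0.02  # per degree
    noc: float = 0.45  # per curve
    mld: float = -0.60  # per mm
    sfar_gt_1: float = 0.70  # indicator
    cag_ge_iii: float = 0.50  # indicator
    intercept: Optional[float] = None  # None → calibrated to incidence

    def linear_predictor(self, soa, noc, mld, sfar_gt_1, cag_ge_iii):
        """β·x without the intercept (vectorized)."""
        return (self.soa * np.asarray(soa, dtype=float)
                + self.noc * np.asarray(noc, dtype=float)
                + self.mld * np.asarray(mld, dtype=float)
                + self.sfar_gt_1 * np.asarray(sfar_gt_1, dtype=float)
                + self.cag_ge_iii * np.asarray(cag_ge_iii, dtype=float))


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-generator configuration; defaults are the study conditions
    the rest of the package is tested under."""

    n_patients: int = 1000
    seed: int = 0
    incidence_target: float = 0.072
    high_risk_fraction: float = 0.20  # latent high-risk-anatomy share
    ideal_length_mean: float = 205.0  # mm
    ideal_length_sd: float = 13.0  # mm
    mld_floor: float = 3.0  # mm
    angle_clip: tuple = (18.0, 85.0)  # degrees, keeps curves detectable
    sheath_od_mean: float = 5.9  # mm (outer diameter)
    sheath_od_sd: float = 0.6
    sheath_od_clip: tuple = (4.0, 7.5)
    jitter_sd: float = 0.03  # mm coordinate noise
    control: StratumParams = CONTROL_STRATUM
    high_risk: StratumParams = HIGH_RISK_STRATUM
    betas: OutcomeBetas = field(default_factory=OutcomeBetas)

    def __post_init__(self):
        if not 0 < self.incidence_target < 1:
            raise InvalidInputError("incidence_target must be in (0, 1)")
        if not 0 <= self.high_risk_fraction <= 1:
            raise InvalidInputError("high_risk_fraction must be in [0, 1]")
        for name in ("ideal_length_mean", "ideal_length_sd", "mld_floor",
                     "sheath_od_mean", "sheath_od_sd"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")
        if self.n_patients < 1:
            raise InvalidInputError("n_patients must be >= 1")


def patient_rng(config: SimulationConfig, index: int) -> np.random.Generator:
    """Independent, reproducible random stream for one patient."""
    return np.random.default_rng(
        np.random.SeedSequence(config.seed,
                               spawn_key=(STREAM_PATIENT, index)))


# ---------------------------------------------------------------------------
# vessel geometry


def _perp_basis(d: np.ndarray):
    ref = np.array([0.0, 0.0, 1.0])
    if abs(d[2]) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def _rodrigues(v: np.ndarray, axis: np.ndarray, phi) -> np.ndarray:
    """Rotate the single vector ``v`` about the unit ``axis`` by each
    angle in ``phi``; returns an (len(phi), 3) array."""
    phi = np.atleast_1d(np.asarray(phi, dtype=float))[:, None]
    cross = np.cross(axis, v)
    dot = float(np.dot(v, axis))
    return (v * np.cos(phi) + cross * np.sin(phi)
            + axis * dot * (1.0 - np.cos(phi)))


def _sample_piecewise(pieces, spacing=1.0):
    """Emit points every ``spacing`` mm along a list of path pieces.

    Each piece is ``('straight', p0, d, L)`` or
    ``('arc', p0, d, axis, radius, theta)``; the final endpoint is always
    included.
    """
    total = sum(p[3] if p[0] == "straight" else p[4] * p[5] for p in pieces)
    s_global = np.arange(0.0, total, spacing)
    if total - s_global[-1] > 1e-9:
        s_global = np.append(s_global, total)
    pts = np.empty((len(s_global), 3))
    offset = 0.0
    k = 0
    for pi, piece in enumerate(pieces):
        if piece[0] == "straight":
            _, p0, d, length = piece
        else:
            _, p0, d, axis, radius, theta = piece
            length = radius * theta
        hi = offset + length
        # samples strictly inside this piece (last piece takes the end)
        end = len(s_global) if pi == len(pieces) - 1 else \
            int(np.searchsorted(s_global, hi, side="left"))
        local = s_global[k:end] - offset
        if len(local):
            if piece[0] == "straight":
                pts[k:end] = p0 + np.outer(local, d)
            else:
                center = p0 + radius * np.cross(axis, d)
                rel = p0 - center
                phi = local / radius
                pts[k:end] = center + _rodrigues(rel, axis, phi)
        k = end
        offset = hi
    return pts[:k]


def _build_vessel_path(angles_deg, rng, length_scale=1.0):
    """Straight runs joined at sharp planar elbows with the given turn
    angles.

    A sharp vertex makes the planted angle the exact chord-probe turning
    angle, so the measurement pipeline can recover it; straights of
    ≥ 30 mm keep neighbouring curves from merging.  Each elbow plane is
    rotated by a random angle about the local vessel axis for 3D realism.
    Returns the point array sampled at 1 mm arc steps.
    """
    p = np.zeros(3)
    d = np.array([0.0, 0.0, 1.0])
    pieces = []
    # a straight vessel is a single full-length run; lengths are rounded
    # to whole mm so elbow vertices land on 1 mm sample points
    lead = round((rng.uniform(25.0, 40.0) if len(angles_deg) else 205.0)
                 * length_scale)
    pieces.append(("straight", p.copy(), d.copy(), float(lead)))
    p = p + lead * d
    for ang in angles_deg:
        theta = math.radians(ang)
        e1, e2 = _perp_basis(d)
        psi = rng.uniform(0.0, 2.0 * math.pi)
        axis = math.cos(psi) * e1 + math.sin(psi) * e2
        d = _rodrigues(d, axis, theta)[0]
        gap = round(rng.uniform(30.0, 55.0) * length_scale)
        pieces.append(("straight", p.copy(), d.copy(), float(gap)))
        p = p + gap * d
    return _sample_piecewise(pieces, spacing=1.0)


def _diameter_profile(n_points, arc, mld, rng):
    """Smooth baseline diameter with one Gaussian stenotic dip whose
    minimum equals ``mld`` exactly at a grid point."""
    base = mld + rng.uniform(0.8, 2.2)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    profile = base + 0.2 * np.sin(2.0 * math.pi * arc / 80.0 + phase)
    dip_idx = int(rng.integers(5, n_points - 5))
    depth = profile[dip_idx] - mld
    profile = profile - depth * np.exp(-((arc - arc[dip_idx]) ** 2)
                                       / (2.0 * 5.0 ** 2))
    profile[dip_idx] = mld  # exact by construction
    return profile, dip_idx


def _draw_plaques(rng, stratum: StratumParams, arc, diameters):
    if rng.random() >= stratum.p_plaque:
        return []
    total = arc[-1]
    center = float(rng.uniform(0.15, 0.85) * total)
    half = rng.uniform(5.0, 9.0)
    lo = max(0.0, center - half)
    hi = min(total, center + half)
    pos_draw = rng.random()
    if pos_draw < 0.4:
        position = PlaquePosition.INNER_WALL
    elif pos_draw < 0.8:
        position = PlaquePosition.OUTER_WALL
    else:
        position = PlaquePosition.CIRCUMFERENTIAL
    if rng.random() < stratum.p_cat3_given_plaque:
        lumen_fraction = rng.uniform(0.5, 0.85)
    else:
        lumen_fraction = rng.uniform(0.05, 0.45)
    if position is PlaquePosition.CIRCUMFERENTIAL:
        perimeter_fraction = rng.uniform(0.8, 1.0)
    else:
        perimeter_fraction = rng.uniform(0.1, 0.7)
    in_span = (arc >= lo) & (arc <= hi)
    local_radius = float(diameters[in_span].min()) / 2.0
    thickness = rng.uniform(0.10, 0.28) * local_radius
    return [Plaque(span=(lo, hi), position=position,
                   perimeter_fraction=perimeter_fraction,
                   lumen_fraction=lumen_fraction, thickness=thickness)]


def simulate_vessel(config: SimulationConfig, rng: np.random.Generator,
                    stratum: Optional[StratumParams] = None,
                    n_curves: Optional[int] = None):
    """Generate one synthetic vessel.

    Returns ``(centerline, plaques, planted)`` where ``planted`` records
    the ground truth (``noc``, per-curve ``angles``, ``soa``, ``mld``) so
    tests can check that the measurement pipeline recovers it.
    ``n_curves=0`` forces a straight vessel.
    """
    if stratum is None:
        stratum = config.control
    if n_curves is None:
        n_curves = 2 + int(rng.poisson(stratum.noc_poisson_mean))
    if n_curves > 0:
        scale = stratum.angle_mean / stratum.angle_shape
        angles = rng.gamma(stratum.angle_shape, scale, size=n_curves)
        angles = np.clip(angles, *config.angle_clip)
    else:
        angles = np.zeros(0)
    length_scale = rng.normal(config.ideal_length_mean,
                              config.ideal_length_sd) / 205.0
    length_scale = max(0.5, length_scale)
    pts = _build_vessel_path(angles, rng, length_scale=length_scale)
    if config.jitter_sd > 0:
        pts = pts + rng.normal(0.0, config.jitter_sd, size=pts.shape)

    mld = max(config.mld_floor,
              rng.normal(stratum.mld_mean, stratum.mld_sd))
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    dia, _ = _diameter_profile(len(pts), arc, mld, rng)

    cl = Centerline.from_arrays(pts, dia,
                                landmarks={PUNCTURE: 0,
                                           BIFURCATION: len(pts) - 1})
    plaques = _draw_plaques(rng, stratum, arc, dia)
    planted = {"noc": int(n_curves), "angles": np.asarray(angles),
               "soa": float(np.sum(angles)), "mld": float(mld)}
    return cl, plaques, planted


# ---------------------------------------------------------------------------
# outcome mechanism


def outcome_probability(features: dict, betas: OutcomeBetas,
                        intercept: Optional[float] = None):
    """Logistic probability of an IVC given extracted features.

    ``features`` holds ``soa``, ``noc``, ``mld``, ``sfar_gt_1``,
    ``cag_ge_iii`` (scalars or arrays).  The intercept comes from
    ``betas.intercept`` unless overridden.
    """
    if intercept is None:
        intercept = betas.intercept
    if intercept is None:
        raise InvalidInputError(
            "no intercept: pass one or calibrate the betas first")
    lp = betas.linear_predictor(features["soa"], features["noc"],
                                features["mld"], features["sfar_gt_1"],
                                features["cag_ge_iii"])
    return expit(intercept + lp)


def _latent_features(config: SimulationConfig, n: int,
                     rng: np.random.Generator):
    """Fast vectorized draw of the latent feature distribution (no
    geometry) — used only to calibrate the intercept."""
    strat = rng.random(n) < config.high_risk_fraction
    lam = np.where(strat, config.high_risk.noc_poisson_mean,
                   config.control.noc_poisson_mean)
    noc = 2 + rng.poisson(lam)
    mean = np.where(strat, config.high_risk.angle_mean,
                    config.control.angle_mean)
    shape = np.where(strat, config.high_risk.angle_shape,
                     config.control.angle_shape)
    per_curve_mean = np.repeat(mean, noc)
    per_curve_shape = np.repeat(shape, noc)
    ang = rng.gamma(per_curve_shape, per_curve_mean / per_curve_shape)
    ang = np.clip(ang, *config.angle_clip)
    starts = np.concatenate([[0], np.cumsum(noc)[:-1]])
    soa = np.add.reduceat(ang, starts)
    mld = np.maximum(config.mld_floor,
                     rng.normal(np.where(strat, config.high_risk.mld_mean,
                                         config.control.mld_mean),
                                np.where(strat, config.high_risk.mld_sd,
                                         config.control.mld_sd)))
    sheath = np.clip(rng.normal(config.sheath_od_mean, config.sheath_od_sd,
                                n), *config.sheath_od_clip)
    sfar_gt_1 = (sheath / mld) > 1.0
    p3 = np.where(strat, config.high_risk.p_cat3_given_plaque,
                  config.control.p_cat3_given_plaque)
    p_pl = np.where(strat, config.high_risk.p_plaque,
                    config.control.p_plaque)
    cag = rng.random(n) < p_pl * p3
    return {"soa": soa, "noc": noc, "mld": mld, "sfar_gt_1": sfar_gt_1,
            "cag_ge_iii": cag}


def calibrate_intercept(config: SimulationConfig,
                        n: int = 100_000) -> float:
    """Intercept making the mean outcome probability equal the target
    incidence over a large latent-feature draw."""
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed,
                               spawn_key=(STREAM_CALIBRATION,)))
    feats = _latent_features(config, n, rng)
    lp = config.betas.linear_predictor(feats["soa"], feats["noc"],
                                       feats["mld"], feats["sfar_gt_1"],
                                       feats["cag_ge_iii"])

    def gap(c):
        return float(np.mean(expit(c + lp))) - config.incidence_target

    return brentq(gap, -30.0, 10.0, xtol=1e-10)


def calibrated(config: SimulationConfig) -> SimulationConfig:
    """Return the config with ``betas.intercept`` filled in (no-op when
    already set)."""
    if config.betas.intercept is not None:
        return config
    c = calibrate_intercept(config)
    return replace(config, betas=replace(config.betas, intercept=c))


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a full synthetic cohort table.

    Every feature column (SOA, NOC, MLD, IFT, SFAR, CSI, calcification
    category …) is *measured* by running the geometry pipeline on each
    generated vessel; outcomes are Bernoulli draws from the logistic
    mechanism evaluated on those measured features.
    """
    config = calibrated(config)
    rows = []
    for i in range(config.n_patients):
        rng = patient_rng(config, i)
        high = rng.random() < config.high_risk_fraction
        stratum = config.high_risk if high else config.control
        cl, plaques, planted = simulate_vessel(config, rng, stratum=stratum)
        sheath = float(np.clip(rng.normal(config.sheath_od_mean,
                                          config.sheath_od_sd),
                               *config.sheath_od_clip))
        prof, lum, curves, _ = analyze(cl)
        category = max((int(p.category) for p in plaques), default=1)
        sfar_v = sfar_ratio(sheath, lum.mld)
        csi_v = prof.sum_of_angles * prof.n_curves / lum.mld
        feats = {"soa": prof.sum_of_angles, "noc": prof.n_curves,
                 "mld": lum.mld, "sfar_gt_1": float(sfar_v > 1.0),
                 "cag_ge_iii": float(category >= 3)}
        lp = float(config.betas.linear_predictor(
            feats["soa"], feats["noc"], feats["mld"], feats["sfar_gt_1"],
            feats["cag_ge_iii"]))
        p = float(expit(config.betas.intercept + lp))
        outcome = int(rng.random() < p)
        ivc_type = None
        if outcome:
            ivc_type = IVC_TYPES[int(rng.choice(len(IVC_TYPES),
                                                p=IVC_TYPE_PROBS))]
        age = float(rng.normal(81.0, 8.0))
        sex = int(rng.random() < 0.52)  # 1 = female
        pad = int(rng.random() < (0.24 if high else 0.13))
        valve = ("self_expanding" if rng.random() < 0.22
                 else "balloon_expandable")
        rows.append({
            "id": i, "age": age, "sex": sex,
            "peripheral_artery_disease": pad,
            "sheath_size_gt14F": int(sheath > 5.7),
            "valve_type": valve, "sheath_od_mm": sheath,
            "soa": prof.sum_of_angles, "noc": prof.n_curves,
            "max_angle": prof.max_angle, "mld": lum.mld,
            "min_area": lum.min_area, "min_perimeter": lum.min_perimeter,
            "mean_diameter": lum.mean_diameter, "ift": prof.ift,
            "sfar": sfar_v, "csi": csi_v, "calc_category": category,
            "cag_ge_iii": int(category >= 3),
            "sfar_gt_1": int(sfar_v > 1.0),
            "linear_predictor": config.betas.intercept + lp,
            "outcome": outcome, "ivc_type": ivc_type,
            "planted_noc": planted["noc"], "planted_soa": planted["soa"],
            "planted_mld": planted["mld"],
            "high_risk_stratum": int(high),
        })
    return pd.DataFrame(rows).set_index("id")
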