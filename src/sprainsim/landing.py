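"""Reduced-order forward dynamics of a single-limb drop landing.

The model has three degrees of freedom: vertical translation of a lumped
body mass, talocrural rotation (dorsiflexion +) about a tibia-fixed axis,
and subtalar rotation (supination +) about a talus-fixed oblique axis.  The
foot contacts a possibly inclined platform through an elastic-foundation
model (four sole points, pressure proportional to interpenetration with a
velocity-dependent dissipation term, never tensile).  Joint moments come
from an uncoupled passive bushing, an optional brace bushing acting in
parallel, a stretch-reflex/co-activation muscle controller on the subtalar
axis, gravity, and light viscous joint damping.

Integration is fixed-step classical Runge-Kutta with a sample-indexed
history buffer for the reflex latency; the reflex torque is held constant
within each step.  Identical inputs produce bit-identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Mapping

import numpy as np
import pandas as pd

from .kinematics import (AxisSet, GimbalLockError, JointAngles,
                         compose_ankle_orientation, jcs_decompose,
                         project_moment_set, rotation_about_axis)

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    def _jit(f):
        return _njit(cache=False)(f)
except Exception:  # pragma: no cover
    def _jit(f):
        return f

__all__ = [
    "SimulationInputs",
    "ModelParameters",
    "PassiveBushingModel",
    "BraceModel",
    "ContactModel",
    "MuscleController",
    "Trajectory",
    "PeakOutcomes",
    "SimulationDivergedError",
    "passive_torque",
    "brace_torque",
    "contact_normal_force",
    "muscle_moment",
    "simulate_drop_landing",
    "extract_peak_outcomes",
    "write_trajectory_csv",
]

_G = 9.81


class SimulationDivergedError(RuntimeError):
    """Integrator produced a non-finite state; carries the last valid time."""

    def __init__(self, message: str, last_valid_time_s: float):
        super().__init__(message)
        self.last_valid_time_s = last_valid_time_s


# ---------------------------------------------------------------------------
# Inputs and fixed model parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationInputs:
    """The ten per-trial parameters of one model evaluation plus the fixed
    platform incline.

    ``talocrural_contact_deg`` is plantarflexion-positive (the convention
    used when specifying landing posture) and is negated internally to the
    dorsiflexion-positive state variable.  ``brace_scale_pct`` of 0 means no
    brace; 100 duplicates the passive anatomy; larger values are stiffer.
    """

    incline_deg: float = 30.0
    brace_scale_pct: float = 0.0
    coactivation_pct: float = 0.0
    reflex_gain: float = 0.0
    strength_pct: float = 100.0
    passive_flexibility_pct: float = 100.0
    talocrural_contact_deg: float = 34.0
    subtalar_contact_deg: float = 0.0
    drop_height_m: float = 0.30
    contact_modulus_MPa_per_m: float = 50.0
    contact_dissipation_s_per_m: float = 5.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v!r}")
        if self.drop_height_m < 0:
            raise ValueError("drop_height_m must be >= 0")
        for name in ("brace_scale_pct", "coactivation_pct", "strength_pct",
                     "passive_flexibility_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.passive_flexibility_pct <= 0:
            raise ValueError("passive_flexibility_pct must be > 0")
        if self.contact_modulus_MPa_per_m <= 0:
            raise ValueError("contact_modulus_MPa_per_m must be > 0")

    @classmethod
    def from_record(cls, record: Mapping[str, float],
                    incline_deg: float) -> "SimulationInputs":
        return cls(incline_deg=incline_deg, **{k: float(v)
                                               for k, v in record.items()})


@dataclass(frozen=True)
class ModelParameters:
    """Fixed structural constants of the reduced model.

    The lumped mass and baseline anthropometry follow a 68 kg subject; the
    bushing coefficients place roughly 25 N m of passive restoring torque
    near 45-50 deg of supination.  All defaults are documented in the
    methods note.
    """

    body_mass_kg: float = 68.0
    foot_mass_kg: float = 1.0
    inertia_talocrural_kgm2: float = 0.012
    inertia_subtalar_kgm2: float = 0.008
    # sole contact points in the foot frame (X anterior, Y up, Z lateral):
    # medial/lateral heel, medial/lateral forefoot; ankle at the origin.
    contact_points_m: tuple = ((-0.05, -0.09, -0.04), (-0.05, -0.09, 0.04),
                               (0.15, -0.09, -0.04), (0.15, -0.09, 0.04))
    contact_area_m2: float = 0.004
    foot_com_m: tuple = (0.06, -0.05, 0.0)
    friction_coefficient: float = 0.9
    friction_regularisation_m_s: float = 0.05
    # double-exponential bushing tau(x) = A(e^-Bx - 1) - C(e^Dx - 1), x deg
    bushing_A_Nm: float = 0.227
    bushing_B_per_deg: float = 0.10
    bushing_C_Nm: float = 0.227
    bushing_D_per_deg: float = 0.10
    joint_damping_Nms_per_rad: float = 2.0
    tau_max_evertor_Nm: float = 60.0
    tau_max_invertor_Nm: float = 60.0
    coactivation_stiffness_per_deg: float = 0.02
    k_reflex_Nm_per_deg: float = 0.05
    reflex_latency_s: float = 0.060
    activation_time_constant_s: float = 0.040
    dt_s: float = 1.0e-4
    window_s: float = 0.30
    output_hz: float = 2000.0


DEFAULT_PARAMETERS = ModelParameters()


# ---------------------------------------------------------------------------
# Component torque laws
# ---------------------------------------------------------------------------

def _tau_base(angle_deg, A, B, C, D):
    """Baseline double-exponential bushing torque (restoring, odd for the
    default A=C, B=D)."""
    return (A * (np.exp(-B * angle_deg) - 1.0)
            - C * (np.exp(D * angle_deg) - 1.0))


def _tau_base_antideriv(angle_deg, A, B, C, D):
    """Antiderivative of ``_tau_base`` in N m deg (zero at zero)."""
    return (A * (-(1.0 / B) * np.exp(-B * angle_deg) - angle_deg + 1.0 / B)
            - C * ((1.0 / D) * np.exp(D * angle_deg) - angle_deg - 1.0 / D))


@dataclass(frozen=True)
class PassiveBushingModel:
    """Uncoupled, rotation-only passive ankle bushing.

    ``flexibility_pct`` rescales the displacement axis of the baseline
    torque-angle curve: at 50% flexibility the joint reaches a given torque
    at half the baseline excursion.
    """

    A_Nm: float = DEFAULT_PARAMETERS.bushing_A_Nm
    B_per_deg: float = DEFAULT_PARAMETERS.bushing_B_per_deg
    C_Nm: float = DEFAULT_PARAMETERS.bushing_C_Nm
    D_per_deg: float = DEFAULT_PARAMETERS.bushing_D_per_deg
    flexibility_pct: float = 100.0

    def __post_init__(self):
        if self.flexibility_pct <= 0:
            raise ValueError("flexibility_pct must be > 0")

    def torque(self, angle_deg):
        s = 100.0 / self.flexibility_pct
        return _tau_base(np.asarray(angle_deg, float) * s,
                         self.A_Nm, self.B_per_deg, self.C_Nm, self.D_per_deg)

    def strain_energy_J(self, angle_deg):
        """Elastic energy stored at the given angle, in joules."""
        s = 100.0 / self.flexibility_pct
        u_deg = -_tau_base_antideriv(np.asarray(angle_deg, float) * s,
                                     self.A_Nm, self.B_per_deg,
                                     self.C_Nm, self.D_per_deg) / s
        return u_deg * math.pi / 180.0


@dataclass(frozen=True)
class BraceModel:
    """External brace bushing acting in parallel with passive anatomy.

    The brace torque law references the same baseline curve with the
    displacement axis divided by ``brace_scale_pct``/100: a 150% brace
    reaches a given torque at 2/3 of the baseline excursion (stiffer than
    anatomy); scale 0 removes the brace entirely.
    """

    brace_scale_pct: float = 0.0
    A_Nm: float = DEFAULT_PARAMETERS.bushing_A_Nm
    B_per_deg: float = DEFAULT_PARAMETERS.bushing_B_per_deg
    C_Nm: float = DEFAULT_PARAMETERS.bushing_C_Nm
    D_per_deg: float = DEFAULT_PARAMETERS.bushing_D_per_deg

    def __post_init__(self):
        if self.brace_scale_pct < 0:
            raise ValueError("brace_scale_pct must be >= 0")

    def torque(self, angle_deg):
        if self.brace_scale_pct == 0.0:
            return np.zeros_like(np.asarray(angle_deg, float)) + 0.0
        s = self.brace_scale_pct / 100.0
        return _tau_base(np.asarray(angle_deg, float) * s,
                         self.A_Nm, self.B_per_deg, self.C_Nm, self.D_per_deg)

    def strain_energy_J(self, angle_deg):
        if self.brace_scale_pct == 0.0:
            return np.zeros_like(np.asarray(angle_deg, float)) + 0.0
        s = self.brace_scale_pct / 100.0
        u_deg = -_tau_base_antideriv(np.asarray(angle_deg, float) * s,
                                     self.A_Nm, self.B_per_deg,
                                     self.C_Nm, self.D_per_deg) / s
        return u_deg * math.pi / 180.0


def passive_torque(angle_deg, flexibility_pct: float,
                   params: ModelParameters = DEFAULT_PARAMETERS):
    """Passive bushing torque (N m) at the given angle (deg).

    Flexibility rescales the displacement axis: tau(theta) =
    tau_base(theta * 100 / flexibility_pct).
    """
    if not flexibility_pct > 0:
        raise ValueError("flexibility_pct must be > 0")
    return PassiveBushingModel(params.bushing_A_Nm, params.bushing_B_per_deg,
                               params.bushing_C_Nm, params.bushing_D_per_deg,
                               flexibility_pct).torque(angle_deg)


def brace_torque(angle_deg, brace_scale_pct: float,
                 params: ModelParameters = DEFAULT_PARAMETERS):
    """Brace bushing torque (N m); scale 0 means no brace, 100 duplicates
    the baseline passive curve, larger scales are stiffer."""
    if brace_scale_pct < 0:
        raise ValueError("brace_scale_pct must be >= 0")
    return BraceModel(brace_scale_pct, params.bushing_A_Nm,
                      params.bushing_B_per_deg, params.bushing_C_Nm,
                      params.bushing_D_per_deg).torque(angle_deg)


def contact_normal_force(penetration_m: float, penetration_rate_m_s: float,
                         modulus_MPa_per_m: float, dissipation_s_per_m: float,
                         area_m2: float) -> float:
    """Elastic-foundation normal force at one contact point (N).

    f = max(0, area * modulus * penetration * (1 + dissipation * rate)),
    zero without penetration and clamped so it is never tensile.
    """
    if not all(math.isfinite(v) for v in (penetration_m, penetration_rate_m_s,
                                          modulus_MPa_per_m,
                                          dissipation_s_per_m, area_m2)):
        raise ValueError("contact parameters must be finite")
    if modulus_MPa_per_m <= 0 or area_m2 <= 0:
        raise ValueError("modulus and area must be > 0")
    if penetration_m <= 0.0:
        return 0.0
    f = (area_m2 * modulus_MPa_per_m * 1.0e6 * penetration_m
         * (1.0 + dissipation_s_per_m * penetration_rate_m_s))
    return f if f > 0.0 else 0.0


@dataclass(frozen=True)
class ContactModel:
    """Elastic-foundation sole contact: point layout, per-point area, and
    the modulus/dissipation pair of the pressure law."""

    modulus_MPa_per_m: float = 50.0
    dissipation_s_per_m: float = 5.0
    points_m: tuple = DEFAULT_PARAMETERS.contact_points_m
    area_m2: float = DEFAULT_PARAMETERS.contact_area_m2

    def normal_force(self, penetration_m, penetration_rate_m_s):
        return contact_normal_force(penetration_m, penetration_rate_m_s,
                                    self.modulus_MPa_per_m,
                                    self.dissipation_s_per_m, self.area_m2)

    @property
    def stiffness_N_per_m(self) -> float:
        return self.area_m2 * self.modulus_MPa_per_m * 1.0e6


@dataclass(frozen=True)
class MuscleController:
    """Stretch-reflex / co-activation torque controller on the subtalar
    axis (supination-positive coordinates; evertors act toward pronation,
    i.e. negatively).

    The net moment has two channels.  The neural channel — a constant
    invertor/evertor co-activation bias plus a delayed reflex proportional
    to supination excursion beyond the contact posture — is bounded by
    strength-scaled maximum evertor/invertor torques.  The intrinsic
    channel is the short-range stiffness of the co-activated muscle pair,
    an activation-proportional mechanical impedance about the contact
    posture that is pre-engaged at contact and adds to the neural torque
    (it is not a motor command and is not clipped by the neural cap).
    """

    coactivation_pct: float = 0.0
    reflex_gain: float = 0.0
    strength_pct: float = 100.0
    tau_max_evertor_Nm: float = DEFAULT_PARAMETERS.tau_max_evertor_Nm
    tau_max_invertor_Nm: float = DEFAULT_PARAMETERS.tau_max_invertor_Nm
    reflex_latency_s: float = DEFAULT_PARAMETERS.reflex_latency_s
    k_reflex_Nm_per_deg: float = DEFAULT_PARAMETERS.k_reflex_Nm_per_deg
    coactivation_stiffness_per_deg: float = (
        DEFAULT_PARAMETERS.coactivation_stiffness_per_deg)
    reference_posture_deg: float = 0.0

    def moment(self, current_deg: float, delayed_deg: float) -> float:
        a = self.coactivation_pct / 100.0
        s = self.strength_pct / 100.0
        cap_ev = s * self.tau_max_evertor_Nm
        cap_inv = s * self.tau_max_invertor_Nm
        bias = a * s * (self.tau_max_invertor_Nm - self.tau_max_evertor_Nm)
        k_co = (a * s * 0.5
                * (self.tau_max_evertor_Nm + self.tau_max_invertor_Nm)
                * self.coactivation_stiffness_per_deg)
        exc_delayed = delayed_deg - self.reference_posture_deg
        reflex = -self.reflex_gain * self.k_reflex_Nm_per_deg * max(
            0.0, exc_delayed)
        neural = min(cap_inv, max(-cap_ev, bias + reflex))
        intrinsic = -k_co * (current_deg - self.reference_posture_deg)
        return neural + intrinsic


def muscle_moment(state_history: np.ndarray, t: float,
                  controller: MuscleController) -> float:
    """Net subtalar muscle moment (N m) at time ``t``.

    ``state_history`` is an (N, 2) array of [time_s, subtalar_deg] samples
    covering at least [t - latency, t].  When the history does not yet reach
    back a full latency, the contact (reference) posture stands in for the
    delayed signal.
    """
    hist = np.asarray(state_history, dtype=float)
    if hist.ndim != 2 or hist.shape[1] != 2 or hist.shape[0] == 0:
        raise ValueError("state_history must be a non-empty (N, 2) array")
    current = float(np.interp(t, hist[:, 0], hist[:, 1]))
    t_del = t - controller.reflex_latency_s
    if t_del < hist[0, 0]:
        delayed = controller.reference_posture_deg
    else:
        delayed = float(np.interp(t_del, hist[:, 0], hist[:, 1]))
    return controller.moment(current, delayed)


# ---------------------------------------------------------------------------
# Integrator core (numba-compiled when available)
# ---------------------------------------------------------------------------

# packed-parameter indices
_NY, _NZ, _KA, _CD, _MT, _MF, _I1, _I2, _GR = range(9)
_BA, _BB, _BC, _BD, _FS, _BS = range(9, 15)
_CB, _CK, _RG, _CEV, _CIN, _T2REF, _B1, _B2, _DT = range(15, 24)
_A1X, _A1Y, _A1Z, _A2X, _A2Y, _A2Z, _CMX, _CMY, _CMZ = range(24, 33)
_MU, _VREG, _TACT = range(33, 36)
_NPP = 36


@_jit
def _rhs(y, vy, z, vz, th1, w1, th2, w2, act, tau_reflex, pp, pts):
    c1 = math.cos(th1)
    s1 = math.sin(th1)
    c2 = math.cos(th2)
    s2 = math.sin(th2)
    a1x = pp[_A1X]
    a1y = pp[_A1Y]
    a1z = pp[_A1Z]
    a2x = pp[_A2X]
    a2y = pp[_A2Y]
    a2z = pp[_A2Z]
    # subtalar axis in the world frame (rotates with the talus)
    dx1 = a1y * a2z - a1z * a2y
    dy1 = a1z * a2x - a1x * a2z
    dz1 = a1x * a2y - a1y * a2x
    dot1 = a1x * a2x + a1y * a2y + a1z * a2z
    a2wx = a2x * c1 + dx1 * s1 + a1x * dot1 * (1.0 - c1)
    a2wy = a2y * c1 + dy1 * s1 + a1y * dot1 * (1.0 - c1)
    a2wz = a2z * c1 + dz1 * s1 + a1z * dot1 * (1.0 - c1)
    # foot angular velocity
    ox = w1 * a1x + w2 * a2wx
    oy = w1 * a1y + w2 * a2wy
    oz = w1 * a1z + w2 * a2wz
    ny = pp[_NY]
    nz = pp[_NZ]
    fy_tot = 0.0
    fz_tot = 0.0
    mcx = 0.0
    mcy = 0.0
    mcz = 0.0
    for i in range(pts.shape[0]):
        rx = pts[i, 0]
        ry = pts[i, 1]
        rz = pts[i, 2]
        # rotate about subtalar axis, then talocrural axis
        kx = a2y * rz - a2z * ry
        ky = a2z * rx - a2x * rz
        kz = a2x * ry - a2y * rx
        kd = a2x * rx + a2y * ry + a2z * rz
        wxv = rx * c2 + kx * s2 + a2x * kd * (1.0 - c2)
        wyv = ry * c2 + ky * s2 + a2y * kd * (1.0 - c2)
        wzv = rz * c2 + kz * s2 + a2z * kd * (1.0 - c2)
        kx = a1y * wzv - a1z * wyv
        ky = a1z * wxv - a1x * wzv
        kz = a1x * wyv - a1y * wxv
        kd = a1x * wxv + a1y * wyv + a1z * wzv
        px = wxv * c1 + kx * s1 + a1x * kd * (1.0 - c1)
        py = wyv * c1 + ky * s1 + a1y * kd * (1.0 - c1)
        pz = wzv * c1 + kz * s1 + a1z * kd * (1.0 - c1)
        pen = -((y + py) * ny + (z + pz) * nz)
        if pen > 0.0:
            vpx = oy * pz - oz * py
            vpy = vy + (oz * px - ox * pz)
            vpz = vz + (ox * py - oy * px)
            pen_rate = -(vpy * ny + vpz * nz)
            f = pp[_KA] * pen * (1.0 + pp[_CD] * pen_rate)
            if f > 0.0:
                # regularised Coulomb friction opposing sliding
                vn = vpy * ny + vpz * nz
                tx = vpx
                ty = vpy - vn * ny
                tz = vpz - vn * nz
                tmag = math.sqrt(tx * tx + ty * ty + tz * tz
                                 + pp[_VREG] * pp[_VREG])
                ff = -pp[_MU] * f / tmag
                fxv = ff * tx
                fyv = f * ny + ff * ty
                fzv = f * nz + ff * tz
                fy_tot += fyv
                fz_tot += fzv
                mcx += py * fzv - pz * fyv
                mcy += pz * fxv - px * fzv
                mcz += px * fyv - py * fxv
    # gravity moment of the foot about the joint axes
    rx = pp[_CMX]
    ry = pp[_CMY]
    rz = pp[_CMZ]
    kx = a2y * rz - a2z * ry
    ky = a2z * rx - a2x * rz
    kz = a2x * ry - a2y * rx
    kd = a2x * rx + a2y * ry + a2z * rz
    wxv = rx * c2 + kx * s2 + a2x * kd * (1.0 - c2)
    wyv = ry * c2 + ky * s2 + a2y * kd * (1.0 - c2)
    wzv = rz * c2 + kz * s2 + a2z * kd * (1.0 - c2)
    kx = a1y * wzv - a1z * wyv
    ky = a1z * wxv - a1x * wzv
    kz = a1x * wyv - a1y * wxv
    kd = a1x * wxv + a1y * wyv + a1z * wzv
    px = wxv * c1 + kx * s1 + a1x * kd * (1.0 - c1)
    py = wyv * c1 + ky * s1 + a1y * kd * (1.0 - c1)
    pz = wzv * c1 + kz * s1 + a1z * kd * (1.0 - c1)
    fg = -pp[_MF] * pp[_GR]
    mgx = py * 0.0 - pz * fg
    mgz = px * fg - py * 0.0
    # bushing torques (displacement-scaled double exponential, degrees)
    deg = 180.0 / math.pi
    th1d = th1 * deg
    th2d = th2 * deg
    x1 = th1d * pp[_FS]
    x2 = th2d * pp[_FS]
    tp1 = (pp[_BA] * (math.exp(-pp[_BB] * x1) - 1.0)
           - pp[_BC] * (math.exp(pp[_BD] * x1) - 1.0))
    tp2 = (pp[_BA] * (math.exp(-pp[_BB] * x2) - 1.0)
           - pp[_BC] * (math.exp(pp[_BD] * x2) - 1.0))
    tb1 = 0.0
    tb2 = 0.0
    if pp[_BS] > 0.0:
        x1 = th1d * pp[_BS]
        x2 = th2d * pp[_BS]
        tb1 = (pp[_BA] * (math.exp(-pp[_BB] * x1) - 1.0)
               - pp[_BC] * (math.exp(pp[_BD] * x1) - 1.0))
        tb2 = (pp[_BA] * (math.exp(-pp[_BB] * x2) - 1.0)
               - pp[_BC] * (math.exp(pp[_BD] * x2) - 1.0))
    # neural muscle torque: co-activation bias plus the delayed reflex
    # (held per step), bounded by strength-scaled maxima; realised torque
    # follows with first-order activation lag.  The co-activation
    # short-range stiffness is an intrinsic mechanical impedance about the
    # contact posture: pre-engaged at contact and additive to the capped
    # neural channel.
    target = pp[_CB] + tau_reflex
    if target < -pp[_CEV]:
        target = -pp[_CEV]
    elif target > pp[_CIN]:
        target = pp[_CIN]
    tau_intrinsic = -pp[_CK] * (th2d - pp[_T2REF] * deg)
    tau1 = ((mcx + mgx) * a1x + (mcy) * a1y + (mcz + mgz) * a1z
            + tp1 + tb1 - pp[_B1] * w1)
    tau2 = ((mcx + mgx) * a2wx + (mcy) * a2wy + (mcz + mgz) * a2wz
            + tp2 + tb2 + act + tau_intrinsic - pp[_B2] * w2)
    return (vy, -pp[_GR] + fy_tot / pp[_MT], vz, fz_tot / pp[_MT],
            w1, tau1 / pp[_I1], w2, tau2 / pp[_I2],
            (target - act) / pp[_TACT])


@_jit
def _integrate(state0, pp, pts, n_steps, lat_steps):
    out = np.empty((n_steps + 1, 9))
    for j in range(9):
        out[0, j] = state0[j]
    dt = pp[_DT]
    deg = 180.0 / math.pi
    kref = pp[_RG]
    t2ref_d = pp[_T2REF] * deg
    for i in range(n_steps):
        # delayed reflex torque, evertor-directed (negative), held per step
        idel = i - lat_steps
        if idel < 0:
            th2_del_d = t2ref_d
        else:
            th2_del_d = out[idel, 6] * deg
        exc = th2_del_d - t2ref_d
        tau_reflex = -kref * exc if exc > 0.0 else 0.0
        k1 = _rhs(out[i, 0], out[i, 1], out[i, 2], out[i, 3],
                  out[i, 4], out[i, 5], out[i, 6], out[i, 7], out[i, 8],
                  tau_reflex, pp, pts)
        k2 = _rhs(out[i, 0] + 0.5 * dt * k1[0], out[i, 1] + 0.5 * dt * k1[1],
                  out[i, 2] + 0.5 * dt * k1[2], out[i, 3] + 0.5 * dt * k1[3],
                  out[i, 4] + 0.5 * dt * k1[4], out[i, 5] + 0.5 * dt * k1[5],
                  out[i, 6] + 0.5 * dt * k1[6], out[i, 7] + 0.5 * dt * k1[7],
                  out[i, 8] + 0.5 * dt * k1[8], tau_reflex, pp, pts)
        k3 = _rhs(out[i, 0] + 0.5 * dt * k2[0], out[i, 1] + 0.5 * dt * k2[1],
                  out[i, 2] + 0.5 * dt * k2[2], out[i, 3] + 0.5 * dt * k2[3],
                  out[i, 4] + 0.5 * dt * k2[4], out[i, 5] + 0.5 * dt * k2[5],
                  out[i, 6] + 0.5 * dt * k2[6], out[i, 7] + 0.5 * dt * k2[7],
                  out[i, 8] + 0.5 * dt * k2[8], tau_reflex, pp, pts)
        k4 = _rhs(out[i, 0] + dt * k3[0], out[i, 1] + dt * k3[1],
                  out[i, 2] + dt * k3[2], out[i, 3] + dt * k3[3],
                  out[i, 4] + dt * k3[4], out[i, 5] + dt * k3[5],
                  out[i, 6] + dt * k3[6], out[i, 7] + dt * k3[7],
                  out[i, 8] + dt * k3[8], tau_reflex, pp, pts)
        ok = True
        for j in range(9):
            v = out[i, j] + (dt / 6.0) * (k1[j] + 2.0 * k2[j]
                                          + 2.0 * k3[j] + k4[j])
            if not math.isfinite(v):
                ok = False
            out[i + 1, j] = v
        if not ok:
            return out[:i + 1]
    return out


def _pack_parameters(inputs: SimulationInputs,
                     params: ModelParameters,
                     axis_set: AxisSet) -> tuple[np.ndarray, np.ndarray]:
    pp = np.zeros(_NPP)
    # platform normal tilts laterally: the surface drops on the lateral
    # side so the medial border is pushed up first, forcing inversion
    inc = math.radians(inputs.incline_deg)
    pp[_NY] = math.cos(inc)
    pp[_NZ] = math.sin(inc)
    pp[_KA] = params.contact_area_m2 * inputs.contact_modulus_MPa_per_m * 1e6
    pp[_CD] = inputs.contact_dissipation_s_per_m
    pp[_MT] = params.body_mass_kg
    pp[_MF] = params.foot_mass_kg
    pp[_I1] = params.inertia_talocrural_kgm2
    pp[_I2] = params.inertia_subtalar_kgm2
    pp[_GR] = _G
    pp[_BA] = params.bushing_A_Nm
    pp[_BB] = params.bushing_B_per_deg
    pp[_BC] = params.bushing_C_Nm
    pp[_BD] = params.bushing_D_per_deg
    pp[_FS] = 100.0 / inputs.passive_flexibility_pct
    pp[_BS] = inputs.brace_scale_pct / 100.0
    a = inputs.coactivation_pct / 100.0
    s = inputs.strength_pct / 100.0
    pp[_CB] = a * s * (params.tau_max_invertor_Nm - params.tau_max_evertor_Nm)
    pp[_CK] = (a * s * 0.5
               * (params.tau_max_evertor_Nm + params.tau_max_invertor_Nm)
               * params.coactivation_stiffness_per_deg)
    pp[_RG] = inputs.reflex_gain * params.k_reflex_Nm_per_deg
    pp[_CEV] = s * params.tau_max_evertor_Nm
    pp[_CIN] = s * params.tau_max_invertor_Nm
    pp[_T2REF] = math.radians(inputs.subtalar_contact_deg)
    pp[_B1] = params.joint_damping_Nms_per_rad
    pp[_B2] = params.joint_damping_Nms_per_rad
    pp[_DT] = params.dt_s
    pp[_MU] = params.friction_coefficient
    pp[_VREG] = params.friction_regularisation_m_s
    pp[_TACT] = params.activation_time_constant_s
    pp[_A1X:_A1Z + 1] = axis_set.talocrural_axis
    pp[_A2X:_A2Z + 1] = axis_set.subtalar_axis
    pp[_CMX:_CMZ + 1] = params.foot_com_m
    pts = np.asarray(params.contact_points_m, dtype=float)
    return pp, pts


# ---------------------------------------------------------------------------
# Trajectory container and simulation driver
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Uniformly sampled landing trajectory (all angles in degrees)."""

    time_s: np.ndarray
    mass_height_m: np.ndarray
    mass_velocity_m_s: np.ndarray
    mass_lateral_m: np.ndarray
    mass_lateral_velocity_m_s: np.ndarray
    talocrural_deg: np.ndarray
    talocrural_velocity_deg_s: np.ndarray
    subtalar_deg: np.ndarray
    subtalar_velocity_deg_s: np.ndarray
    jcs_dorsiflexion_deg: np.ndarray
    jcs_inversion_deg: np.ndarray
    jcs_internal_deg: np.ndarray
    passive_moment_Nm: np.ndarray      # (N, 3) ground frame
    brace_moment_Nm: np.ndarray        # (N, 3) ground frame
    contact_force_N: np.ndarray        # (N,) total normal-force magnitude
    contact_penetration_m: np.ndarray  # (N, n_points)
    inputs: SimulationInputs = None
    axis_set: AxisSet = None
    params: ModelParameters = None

    def __len__(self):
        return self.time_s.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time_s": self.time_s,
            "talocrural_deg": self.talocrural_deg,
            "subtalar_deg": self.subtalar_deg,
            "jcs_dorsiflexion_deg": self.jcs_dorsiflexion_deg,
            "jcs_inversion_deg": self.jcs_inversion_deg,
            "jcs_internal_deg": self.jcs_internal_deg,
            "talocrural_velocity_deg_s": self.talocrural_velocity_deg_s,
            "subtalar_velocity_deg_s": self.subtalar_velocity_deg_s,
            "mass_height_m": self.mass_height_m,
            "mass_velocity_m_s": self.mass_velocity_m_s,
            "mass_lateral_m": self.mass_lateral_m,
            "mass_lateral_velocity_m_s": self.mass_lateral_velocity_m_s,
            "contact_force_N": self.contact_force_N,
        })
        for k, lbl in enumerate("xyz"):
            df[f"passive_moment_{lbl}_Nm"] = self.passive_moment_Nm[:, k]
            df[f"brace_moment_{lbl}_Nm"] = self.brace_moment_Nm[:, k]
        return df


def write_trajectory_csv(trajectory: Trajectory, path) -> None:
    trajectory.to_frame().to_csv(path, index=False, float_format="%.17g")


def simulate_drop_landing(inputs: SimulationInputs,
                          params: ModelParameters = DEFAULT_PARAMETERS,
                          axis_set: AxisSet | None = None) -> Trajectory:
    """Integrate the landing from first ground contact.

    The mass starts with downward speed sqrt(2 g h) and the foot posed at
    the contact joint angles, lowered so the deepest sole point exactly
    touches the platform.  The post-contact window is fixed
    (``params.window_s``); the trajectory is resampled at
    ``params.output_hz``.
    """
    axes = axis_set if axis_set is not None else AxisSet()
    pp, pts = _pack_parameters(inputs, params, axes)
    th1_0 = -math.radians(inputs.talocrural_contact_deg)
    th2_0 = math.radians(inputs.subtalar_contact_deg)
    r0 = (rotation_about_axis(axes.talocrural_axis, math.degrees(th1_0))
          @ rotation_about_axis(axes.subtalar_axis, math.degrees(th2_0)))
    pw = pts @ r0.T
    y0 = float(np.max(-(pw[:, 1] * pp[_NY] + pw[:, 2] * pp[_NZ]) / pp[_NY]))
    vy0 = -math.sqrt(2.0 * _G * inputs.drop_height_m)
    # pre-landing activation settles to the co-activation bias
    act0 = pp[_CB]
    state0 = np.array([y0, vy0, 0.0, 0.0, th1_0, 0.0, th2_0, 0.0, act0])
    n_steps = int(round(params.window_s / params.dt_s))
    lat_steps = int(round(params.reflex_latency_s / params.dt_s))
    states = _integrate(state0, pp, pts, n_steps, lat_steps)
    if states.shape[0] != n_steps + 1:
        raise SimulationDivergedError(
            "non-finite state during integration",
            last_valid_time_s=(states.shape[0] - 1) * params.dt_s)
    stride = max(1, int(round(1.0 / (params.output_hz * params.dt_s))))
    sub = states[::stride]
    t = np.arange(sub.shape[0]) * (params.dt_s * stride)
    return _build_trajectory(t, sub, inputs, params, axes, pp, pts)


def _build_trajectory(t, sub, inputs, params, axes, pp, pts) -> Trajectory:
    n = sub.shape[0]
    th1 = sub[:, 4]
    th2 = sub[:, 6]
    th1_deg = np.degrees(th1)
    th2_deg = np.degrees(th2)
    jcs = np.empty((n, 3))
    passive_m = np.empty((n, 3))
    brace_m = np.empty((n, 3))
    force = np.empty(n)
    pen = np.empty((n, pts.shape[0]))
    a1 = axes.talocrural_axis
    a2 = axes.subtalar_axis
    bushing = PassiveBushingModel(params.bushing_A_Nm, params.bushing_B_per_deg,
                                  params.bushing_C_Nm, params.bushing_D_per_deg,
                                  inputs.passive_flexibility_pct)
    brace = BraceModel(inputs.brace_scale_pct, params.bushing_A_Nm,
                       params.bushing_B_per_deg, params.bushing_C_Nm,
                       params.bushing_D_per_deg)
    nvec = np.array([0.0, pp[_NY], pp[_NZ]])
    for i in range(n):
        r1 = rotation_about_axis(a1, th1_deg[i])
        r2 = rotation_about_axis(a2, th2_deg[i])
        R = r1 @ r2
        try:
            ang = jcs_decompose(R, axes)
            jcs[i] = ang.as_tuple()
        except GimbalLockError:
            jcs[i] = np.nan
        a2w = r1 @ a2
        tp1 = float(bushing.torque(th1_deg[i]))
        tp2 = float(bushing.torque(th2_deg[i]))
        passive_m[i] = tp1 * a1 + tp2 * a2w
        tb1 = float(brace.torque(th1_deg[i]))
        tb2 = float(brace.torque(th2_deg[i]))
        brace_m[i] = tb1 * a1 + tb2 * a2w
        pw = pts @ R.T
        omega = sub[i, 5] * a1 + sub[i, 7] * a2w
        ftot = 0.0
        for j in range(pts.shape[0]):
            p = pw[j]
            d = -((sub[i, 0] + p[1]) * nvec[1] + (sub[i, 2] + p[2]) * nvec[2])
            pen[i, j] = max(0.0, d)
            if d > 0.0:
                vpt = (np.array([0.0, sub[i, 1], sub[i, 3]])
                       + np.cross(omega, p))
                drate = -float(np.dot(vpt, nvec))
                ftot += contact_normal_force(
                    d, drate, inputs.contact_modulus_MPa_per_m,
                    inputs.contact_dissipation_s_per_m, params.contact_area_m2)
        force[i] = ftot
    return Trajectory(
        time_s=t,
        mass_height_m=sub[:, 0],
        mass_velocity_m_s=sub[:, 1],
        mass_lateral_m=sub[:, 2],
        mass_lateral_velocity_m_s=sub[:, 3],
        talocrural_deg=th1_deg,
        talocrural_velocity_deg_s=np.degrees(sub[:, 5]),
        subtalar_deg=th2_deg,
        subtalar_velocity_deg_s=np.degrees(sub[:, 7]),
        jcs_dorsiflexion_deg=jcs[:, 0],
        jcs_inversion_deg=jcs[:, 1],
        jcs_internal_deg=jcs[:, 2],
        passive_moment_Nm=passive_m,
        brace_moment_Nm=brace_m,
        contact_force_N=force,
        contact_penetration_m=pen,
        inputs=inputs,
        axis_set=axes,
        params=params,
    )


# ---------------------------------------------------------------------------
# Peak-outcome extraction
# ---------------------------------------------------------------------------

def _signed_peak(x: np.ndarray) -> float:
    """Value of largest magnitude, keeping its sign; first occurrence wins."""
    i = int(np.nanargmax(np.abs(x)))
    return float(x[i])


@dataclass(frozen=True)
class PeakOutcomes:
    """Peak sprain metrics of one landing.

    The primary outcome is the peak subtalar supination angle; bushing
    moments are reported at the instant of that peak, projected on the
    anatomic and JCS axes; velocities are signed per-axis peaks over the
    whole window.
    """

    peak_subtalar_supination_deg: float
    peak_supination_time_s: float
    peak_talocrural_dorsiflexion_deg: float
    peak_jcs_dorsiflexion_deg: float
    peak_jcs_inversion_deg: float
    peak_jcs_internal_deg: float
    peak_subtalar_velocity_deg_s: float
    peak_talocrural_velocity_deg_s: float
    peak_jcs_dorsiflexion_velocity_deg_s: float
    peak_jcs_inversion_velocity_deg_s: float
    peak_jcs_internal_velocity_deg_s: float
    passive_moment_talocrural_Nm: float
    passive_moment_subtalar_Nm: float
    passive_moment_jcs_sagittal_Nm: float
    passive_moment_jcs_frontal_Nm: float
    passive_moment_jcs_transverse_Nm: float
    brace_moment_talocrural_Nm: float
    brace_moment_subtalar_Nm: float
    brace_moment_jcs_sagittal_Nm: float
    brace_moment_jcs_frontal_Nm: float
    brace_moment_jcs_transverse_Nm: float

    def scalar(self, field_name: str) -> float:
        return float(getattr(self, field_name))

    def to_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


def extract_peak_outcomes(trajectory: Trajectory,
                          axis_set: AxisSet | None = None) -> PeakOutcomes:
    """Extract peak metrics; ties on the peak go to the first sample."""
    if trajectory is None or len(trajectory) == 0:
        raise ValueError("trajectory must be non-empty")
    axes = axis_set if axis_set is not None else (
        trajectory.axis_set or AxisSet())
    th2 = trajectory.subtalar_deg
    i = int(np.argmax(th2))  # argmax returns the first maximal sample
    t_peak = float(trajectory.time_s[i])
    r1 = rotation_about_axis(axes.talocrural_axis, trajectory.talocrural_deg[i])
    R = r1 @ rotation_about_axis(axes.subtalar_axis, th2[i])
    a2w = r1 @ axes.subtalar_axis
    passive = project_moment_set(trajectory.passive_moment_Nm[i], axes,
                                 axes.talocrural_axis, a2w, R).projections
    brace = project_moment_set(trajectory.brace_moment_Nm[i], axes,
                               axes.talocrural_axis, a2w, R).projections
    tgrid = trajectory.time_s
    if len(trajectory) > 1:
        jvel = [np.gradient(x, tgrid) for x in
                (trajectory.jcs_dorsiflexion_deg, trajectory.jcs_inversion_deg,
                 trajectory.jcs_internal_deg)]
    else:
        jvel = [np.zeros(1)] * 3
    return PeakOutcomes(
        peak_subtalar_supination_deg=float(th2[i]),
        peak_supination_time_s=t_peak,
        peak_talocrural_dorsiflexion_deg=float(
            np.max(trajectory.talocrural_deg)),
        peak_jcs_dorsiflexion_deg=float(
            np.nanmax(trajectory.jcs_dorsiflexion_deg)),
        peak_jcs_inversion_deg=float(np.nanmax(trajectory.jcs_inversion_deg)),
        peak_jcs_internal_deg=float(np.nanmax(trajectory.jcs_internal_deg)),
        peak_subtalar_velocity_deg_s=_signed_peak(
            trajectory.subtalar_velocity_deg_s),
        peak_talocrural_velocity_deg_s=_signed_peak(
            trajectory.talocrural_velocity_deg_s),
        peak_jcs_dorsiflexion_velocity_deg_s=_signed_peak(jvel[0]),
        peak_jcs_inversion_velocity_deg_s=_signed_peak(jvel[1]),
        peak_jcs_internal_velocity_deg_s=_signed_peak(jvel[2]),
        passive_moment_talocrural_Nm=passive["talocrural"],
        passive_moment_subtalar_Nm=passive["subtalar"],
        passive_moment_jcs_sagittal_Nm=passive["jcs_sagittal"],
        passive_moment_jcs_frontal_Nm=passive["jcs_frontal"],
        passive_moment_jcs_transverse_Nm=passive["jcs_transverse"],
        brace_moment_talocrural_Nm=brace["talocrural"],
        brace_moment_subtalar_Nm=brace["subtalar"],
        brace_moment_jcs_sagittal_Nm=brace["jcs_sagittal"],
        brace_moment_jcs_frontal_Nm=brace["jcs_frontal"],
        brace_moment_jcs_transverse_Nm=brace["jcs_transverse"],
    )
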