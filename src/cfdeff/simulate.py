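"""Hierarchical synthetic assay data and trace synthesis.

The generator emulates the group-sampling experiments the analysis is
built for: a large pool of bronchial epithelial cells from one patient is
split into cryopreserved aliquots, each aliquot seeds several air-liquid-
interface cultures, and every culture is assayed once after vehicle or
corrector pretreatment.  Responses follow a two-level normal hierarchy per
patient with an additive fixed treatment effect:

    y = arm_mean + a_p (+ g_p on the corrector arm) + b_pj + e_pji

with patient effect a_p ~ N(0, patient_sd^2), patient-specific treatment
deviation g_p ~ N(0, interaction_sd^2), aliquot (group) effect
b_pj ~ N(0, group_sd^2) and culture noise e ~ N(0, within_sd^2).  The
implied true intraclass correlation of one arm is
group_sd^2 / (group_sd^2 + within_sd^2).

Defaults reproduce the reference group-sampling experiment: 23 aliquots of
3-9 cultures per arm, corrector-arm mean 3.3 uA/cm^2, sigma_b^2 = 0.605
and sigma_w^2 = 1.0 (true rho = 0.377).

Per-patient substreams are spawned from the master seed, so adding
patients never perturbs earlier patients' draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .assay import CORRECTOR, VEHICLE, AssayRecord
from .errors import ArgumentError
from .traces import EventTable, IscTrace

_DEFAULT_GROUP_SD = math.sqrt(0.605)


@dataclass(frozen=True)
class SimulationConfig:
    """Hierarchy parameters of the grouped-assay generator (uA/cm^2)."""

    n_patients: int = 1
    patient_sd: float = 0.0
    group_sd: float = _DEFAULT_GROUP_SD
    within_sd: float = 1.0
    vehicle_mean: float = 0.2
    corrector_mean: float = 3.3
    interaction_sd: float = 0.0
    groups_per_patient: int = 23
    group_size_range: tuple[int, int] = (3, 9)
    seed: int = 0
    shared_aliquot_effect: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.group_size_range
        if not (1 <= lo <= hi <= 50):
            raise ArgumentError(
                f"group_size_range must lie within [1, 50], got {self.group_size_range}"
            )
        if self.n_patients < 1 or self.groups_per_patient < 1:
            raise ArgumentError("n_patients and groups_per_patient must be >= 1")
        if self.within_sd <= 0:
            raise ArgumentError("within_sd must be > 0")
        for name in ("patient_sd", "group_sd", "interaction_sd"):
            if getattr(self, name) < 0:
                raise ArgumentError(f"{name} must be >= 0")

    @property
    def true_icc(self) -> float:
        """Intraclass correlation implied by the variance components."""
        return self.group_sd**2 / (self.group_sd**2 + self.within_sd**2)


#: Named presets mirroring the reference experiments.
PRESETS: dict[str, SimulationConfig] = {
    # 170-million-cell pool, 23 aliquots, sizes 3-9, rho = 0.377
    "aliquot-bcf00572-like": SimulationConfig(),
    # 280-million-cell pool, 19 aliquots, eta_o ~ 4.3, rho = 0.2816
    "aliquot-bcf00710-like": SimulationConfig(
        groups_per_patient=19,
        group_size_range=(2, 7),
        group_sd=math.sqrt(0.2816 / (1.0 - 0.2816)),
    ),
    # 20-patient comparison panel, one aliquot per patient, 3 + 3 cultures;
    # components chosen so the corrector-arm total s.d. is 0.962
    "patient-panel-20": SimulationConfig(
        n_patients=20,
        patient_sd=0.68,
        interaction_sd=0.32,
        within_sd=0.60,
        group_sd=0.0,
        groups_per_patient=1,
        group_size_range=(3, 3),
    ),
}


def _patient_records(
    rng: np.random.Generator, config: SimulationConfig, patient_id: str
) -> list[AssayRecord]:
    a_p = rng.normal(0.0, config.patient_sd) if config.patient_sd > 0 else 0.0
    g_p = rng.normal(0.0, config.interaction_sd) if config.interaction_sd > 0 else 0.0
    lo, hi = config.group_size_range
    records: list[AssayRecord] = []
    for j in range(config.groups_per_patient):
        size = int(rng.integers(lo, hi + 1))
        aliquot = f"{patient_id}-A{j + 1:02d}"
        b_veh = rng.normal(0.0, config.group_sd) if config.group_sd > 0 else 0.0
        if config.shared_aliquot_effect:
            b_cor = b_veh
        else:
            b_cor = rng.normal(0.0, config.group_sd) if config.group_sd > 0 else 0.0
        for arm, mean, b in (
            (VEHICLE, config.vehicle_mean + a_p, b_veh),
            (CORRECTOR, config.corrector_mean + a_p + g_p, b_cor),
        ):
            noise = rng.normal(0.0, config.within_sd, size=size)
            for i in range(size):
                records.append(
                    AssayRecord(
                        patient_id=patient_id,
                        aliquot_id=aliquot,
                        treatment=arm,
                        replicate_id=f"r{i + 1:02d}",
                        delta_isc=float(mean + b + noise[i]),
                    )
                )
    return records


def simulate_grouped_assay(config: SimulationConfig) -> list[AssayRecord]:
    """Simulate the aliquot group-sampling experiment.

    Each aliquot contributes equal numbers of vehicle- and corrector-
    treated cultures (the drawn group size applies to each arm).  Aliquot
    effects are drawn independently per treatment arm unless
    shared_aliquot_effect is set.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    records: list[AssayRecord] = []
    for p, child in enumerate(children):
        rng = np.random.default_rng(child)
        records.extend(_patient_records(rng, config, f"P{p + 1:02d}"))
    return records


def simulate_patient_panel(
    config: SimulationConfig, replicates_per_arm: int = 3
) -> list[AssayRecord]:
    """Simulate the multi-patient comparison design: one aliquot per
    patient, a fixed number of vehicle and corrector cultures each.

    The output is a balanced patient x treatment grid suitable for the
    two-way mixed ANOVA and per-patient replicate planning.
    """
    if replicates_per_arm < 1:
        raise ArgumentError("replicates_per_arm must be >= 1")
    panel_cfg = replace(
        config,
        groups_per_patient=1,
        group_size_range=(replicates_per_arm, replicates_per_arm),
    )
    return simulate_grouped_assay(panel_cfg)


@dataclass(frozen=True)
class TraceSynthesisConfig:
    """Shape parameters of a synthetic short-circuit-current recording."""

    #: steady-state post-amiloride I_sc; with ENaC blocked the F508del
    #: baseline sits near zero (a zero baseline also keeps the noiseless
    #: extraction round trip exact in floating point for any amplitude)
    baseline_level: float = 0.0
    response_amplitude: float = 3.3
    noise_sd: float = 0.0
    #: correlation time (s) of the noise process; recording noise is
    #: dominated by slow baseline drift, not white sampling noise (a white
    #: model would bias the peak statistic upward by ~2.7 noise s.d. at
    #: 1 Hz sampling).  0 selects white noise.
    noise_tau: float = 600.0
    pulse_interval: float = 100.0
    pulse_amplitude: float = 8.0
    pulse_width: float = 2.0
    duration: float = 900.0
    sample_dt: float = 1.0
    amiloride_drop: float = 1.0
    fsk_fraction: float = 0.5  # fraction of the response reached before genistein
    rise_time: float = 30.0
    events: tuple[tuple[str, float], ...] = field(
        default_factory=lambda: (
            ("amiloride", 60.0),
            ("forskolin", 180.0),
            ("genistein", 420.0),
            ("inhibitor", 660.0),
            ("atp", 780.0),
        )
    )

    def __post_init__(self) -> None:
        if self.pulse_interval <= 0:
            raise ArgumentError("pulse_interval must be > 0")
        if self.sample_dt <= 0 or self.duration <= self.sample_dt:
            raise ArgumentError("duration must exceed sample_dt > 0")
        times = [t for _, t in self.events]
        if times != sorted(times):
            raise ArgumentError("event schedule must be time-ordered")


def simulate_trace(
    config: TraceSynthesisConfig,
    delta_isc_true: float | None = None,
    seed: int = 0,
    pulses: bool = True,
) -> tuple[IscTrace, EventTable]:
    """Synthesise a recording whose true delta I_sc is exactly known.

    The noiseless trace is flat at the baseline before forskolin, ramps to
    an intermediate forskolin plateau, rises to baseline + delta after
    genistein, and decays exponentially after the inhibitor; resistance-
    check pulse artifacts ride on top at the configured interval.  With
    noise_sd = 0, extract_delta_isc recovers delta_isc_true exactly,
    pulses or not.
    """
    delta = config.response_amplitude if delta_isc_true is None else float(delta_isc_true)
    schedule = dict(config.events)
    for name in ("forskolin", "genistein"):
        if name not in schedule:
            raise ArgumentError(f"trace schedule is missing the {name!r} event")
    t_ami = schedule.get("amiloride", 0.0)
    t_fsk, t_gst = schedule["forskolin"], schedule["genistein"]
    t_inh = schedule.get("inhibitor", config.duration)
    t_atp = schedule.get("atp")

    t = np.arange(0.0, config.duration, config.sample_dt)
    base = config.baseline_level
    current = np.full_like(t, base + config.amiloride_drop)
    current[t >= t_ami] = base
    fsk_level = base + config.fsk_fraction * delta

    ramp1 = (t >= t_fsk) & (t < t_fsk + config.rise_time)
    current[ramp1] = base + (fsk_level - base) * (t[ramp1] - t_fsk) / config.rise_time
    current[(t >= t_fsk + config.rise_time) & (t < t_gst)] = fsk_level

    ramp2 = (t >= t_gst) & (t < t_gst + config.rise_time)
    current[ramp2] = fsk_level + (base + delta - fsk_level) * (
        t[ramp2] - t_gst
    ) / config.rise_time
    current[(t >= t_gst + config.rise_time) & (t < t_inh)] = base + delta

    post = t >= t_inh
    current[post] = base + delta * np.exp(-(t[post] - t_inh) / 60.0)
    if t_atp is not None:
        atp_win = (t >= t_atp) & (t < t_atp + 30.0)
        current[atp_win] += 1.5

    events = list(config.events)
    if pulses:
        tp = config.pulse_interval
        while tp < config.duration:
            sel = (t >= tp) & (t < tp + config.pulse_width)
            current[sel] += config.pulse_amplitude
            events.append(("pulse", float(tp)))
            tp += config.pulse_interval
    if config.noise_sd > 0:
        rng = np.random.default_rng(seed)
        if config.noise_tau > 0:
            # stationary Ornstein-Uhlenbeck drift at sd = noise_sd
            a = math.exp(-config.sample_dt / config.noise_tau)
            innov = rng.normal(
                0.0, config.noise_sd * math.sqrt(1.0 - a * a), size=t.size
            )
            drift = np.empty(t.size)
            drift[0] = rng.normal(0.0, config.noise_sd)
            for i in range(1, t.size):
                drift[i] = a * drift[i - 1] + innov[i]
            current = current + drift
        else:
            current = current + rng.normal(0.0, config.noise_sd, size=t.size)

    return IscTrace(time=t, current=current), EventTable(tuple(events))
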