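"""Variance components for group-sampled assay replicates.

Cultures grown from aliquots of one cell pool are correlated within an
aliquot.  The strength of that clustering is the intraclass correlation
(ICC, rho): the between-group share of total variance, estimated here by
the one-way random-effects ANOVA (method-of-moments) estimator

    rho = (MS_B - MS_W) / (MS_B + (eta_o - 1) MS_W)

where MS_B and MS_W are the between- and within-group mean squares and
eta_o is the effective average group size for unbalanced designs,

    eta_o = (N - sum(n_i^2)/N) / (k - 1).

Clustering inflates the variance of a group-sampled mean by the design
effect 1 + rho (eta_o - 1), the factor by which sample sizes from
independent-sample power calculations must be multiplied.

A balanced two-way mixed patient x treatment ANOVA attributes shares of
the total sum of squares to drug pretreatment, patient, their interaction
(the patient-specific drug response, the quantity of interest for
precision medicine) and residual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .assay import AssayRecord
from .errors import ArgumentError, DegenerateDataError


@dataclass(frozen=True)
class GroupedSample:
    """Responses partitioned into groups (aliquots)."""

    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for label, values in self.groups.items():
            arr = np.asarray(values, dtype=float)
            if arr.size == 0:
                raise ArgumentError(f"group {label!r} is empty")
            clean[str(label)] = arr
        object.__setattr__(self, "groups", clean)

    @classmethod
    def from_records(
        cls,
        records: Sequence[AssayRecord],
        treatment: str | None = None,
        patient: str | None = None,
    ) -> "GroupedSample":
        """Group records by aliquot after filtering to one patient/treatment.

        If after filtering more than one treatment (or patient) remains, the
        grouping would silently mix strata, so this is an error.
        """
        recs = [
            r
            for r in records
            if (treatment is None or r.treatment == treatment)
            and (patient is None or r.patient_id == patient)
        ]
        if not recs:
            raise ArgumentError("no records match the requested patient/treatment")
        treatments = {r.treatment for r in recs}
        patients = {r.patient_id for r in recs}
        if len(treatments) > 1:
            raise ArgumentError(
                f"records span multiple treatments {sorted(treatments)}; "
                "filter to one treatment before grouping"
            )
        if len(patients) > 1:
            raise ArgumentError(
                f"records span multiple patients {sorted(patients)}; "
                "filter to one patient before grouping"
            )
        groups: dict[str, list[float]] = {}
        for r in recs:
            groups.setdefault(r.aliquot_id, []).append(r.delta_isc)
        return cls({k: np.asarray(v) for k, v in groups.items()})

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def sizes(self) -> list[int]:
        return [int(v.size) for v in self.groups.values()]

    @property
    def n_total(self) -> int:
        return sum(self.sizes)

    def pooled(self) -> np.ndarray:
        return np.concatenate(list(self.groups.values()))


@dataclass(frozen=True)
class AnovaOneWay:
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    f: float
    p: float
    degenerate: bool = False

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within

    @property
    def ms_between(self) -> float:
        return self.ss_between / self.df_between

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within

    def to_dict(self) -> dict:
        return {
            "SS_between": self.ss_between,
            "SS_within": self.ss_within,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "MS_between": self.ms_between,
            "MS_within": self.ms_within,
            "F": self.f,
            "p": self.p,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class IccEstimate:
    rho: float
    rho_truncated: float
    eta_o: float
    design_effect: float
    truncated: bool = True

    def to_dict(self) -> dict:
        return {
            "rho": self.rho,
            "rho_truncated": self.rho_truncated,
            "eta_o": self.eta_o,
            "design_effect": self.design_effect,
            "truncated": self.truncated,
        }


def one_way_random_anova(sample: GroupedSample) -> AnovaOneWay:
    """Between/within sums-of-squares decomposition with the F test.

    Groups of size 1 are allowed (they contribute to SS_between only); the
    design needs k >= 2 groups and at least one group with >= 2 members so
    the within mean square exists.
    """
    k = sample.k
    n = sample.n_total
    if k < 2:
        raise ArgumentError(f"one-way ANOVA needs >= 2 groups, got {k}")
    if n < k + 1:
        raise DegenerateDataError(
            "all groups are singletons; the within-group variance is undefined"
        )
    grand = float(np.mean(sample.pooled()))
    ss_b = 0.0
    ss_w = 0.0
    for values in sample.groups.values():
        gmean = float(np.mean(values))
        ss_b += values.size * (gmean - grand) ** 2
        ss_w += float(np.sum((values - gmean) ** 2))
    df_b, df_w = k - 1, n - k
    ms_b, ms_w = ss_b / df_b, ss_w / df_w
    if ms_w > 0:
        f = ms_b / ms_w
        p = float(stats.f.sf(f, df_b, df_w))
        degenerate = False
    else:
        # zero within-group variance: F undefined (or infinite)
        f = math.inf if ms_b > 0 else math.nan
        p = 0.0 if ms_b > 0 else math.nan
        degenerate = True
    return AnovaOneWay(ss_b, ss_w, df_b, df_w, f, p, degenerate)


def effective_group_size(group_sizes: Sequence[int]) -> float:
    """Effective average replicates per group, eta_o, for unbalanced designs.

    eta_o = (N - sum(n_i^2)/N) / (k - 1).  For balanced designs it equals
    the common group size exactly.
    """
    sizes = [int(s) for s in group_sizes]
    if len(sizes) < 2:
        raise ArgumentError("eta_o requires at least 2 groups")
    if any(s < 1 for s in sizes):
        raise ArgumentError("all group sizes must be >= 1")
    n = sum(sizes)
    k = len(sizes)
    return (n - sum(s * s for s in sizes) / n) / (k - 1)


def design_effect(rho: float, eta_o: float) -> float:
    """Variance-inflation factor of group sampling: 1 + rho (eta_o - 1)."""
    if eta_o < 1:
        raise ArgumentError(f"eta_o must be >= 1, got {eta_o}")
    return 1.0 + rho * (eta_o - 1.0)


def icc_from_anova(
    anova: AnovaOneWay, eta_o: float, truncate: bool = True
) -> IccEstimate:
    """ANOVA ICC estimator and the resulting design effect.

    The raw estimate can be negative by sampling noise (down to
    -1/(eta_o - 1)); by default the design effect uses max(rho, 0) so that
    noise never shrinks planned sample sizes below the independent-sample
    answer.  Pass truncate=False to propagate the raw estimate.
    """
    if eta_o <= 1:
        raise ArgumentError(f"icc_from_anova requires eta_o > 1, got {eta_o}")
    ms_b, ms_w = anova.ms_between, anova.ms_within
    if not (math.isfinite(ms_b) and math.isfinite(ms_w)):
        raise DegenerateDataError("mean squares must be finite")
    denom = ms_b + (eta_o - 1.0) * ms_w
    if denom == 0:
        raise DegenerateDataError("both mean squares are zero; ICC undefined")
    rho = (ms_b - ms_w) / denom
    rho_trunc = max(rho, 0.0)
    rho_used = rho_trunc if truncate else rho
    return IccEstimate(
        rho=rho,
        rho_truncated=rho_trunc,
        eta_o=eta_o,
        design_effect=design_effect(rho_used, eta_o),
        truncated=truncate,
    )


@dataclass(frozen=True)
class IccReport:
    """Structured result of the grouping -> ANOVA -> ICC pipeline."""

    patient: str
    treatment: str
    k: int
    n_total: int
    group_sizes: list[int]
    anova: AnovaOneWay
    icc: IccEstimate

    def to_dict(self) -> dict:
        return {
            "patient": self.patient,
            "treatment": self.treatment,
            "k": self.k,
            "N": self.n_total,
            "group_sizes": self.group_sizes,
            "anova": self.anova.to_dict(),
            "icc": self.icc.to_dict(),
        }


def estimate_icc_pipeline(
    records: Sequence[AssayRecord],
    treatment: str,
    patient: str | None = None,
    truncate: bool = True,
) -> IccReport:
    """Grouping -> one-way ANOVA -> eta_o -> ICC -> design effect."""
    sample = GroupedSample.from_records(records, treatment=treatment, patient=patient)
    anova = one_way_random_anova(sample)
    eta = effective_group_size(sample.sizes)
    icc = icc_from_anova(anova, eta, truncate=truncate)
    patients = {r.patient_id for r in records if r.treatment == treatment}
    return IccReport(
        patient=patient if patient is not None else next(iter(patients)),
        treatment=treatment,
        k=sample.k,
        n_total=sample.n_total,
        group_sizes=sample.sizes,
        anova=anova,
        icc=icc,
    )


@dataclass(frozen=True)
class TwoWayPartition:
    percent_treatment: float
    percent_patient: float
    percent_interaction: float
    percent_residual: float
    p_interaction: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "percent_treatment": self.percent_treatment,
            "percent_patient": self.percent_patient,
            "percent_interaction": self.percent_interaction,
            "percent_residual": self.percent_residual,
            "p_interaction": self.p_interaction,
            "degenerate": self.degenerate,
        }


def two_way_mixed_anova(records: Sequence[AssayRecord]) -> TwoWayPartition:
    """Balanced patient x treatment SS decomposition into % of total SS.

    Treatment is the fixed factor, patient the random factor; the
    interaction term quantifies patient-specific drug responses and its F
    test uses the residual mean square.  Only balanced grids (every patient
    x treatment cell filled with the same number of replicates) are
    accepted; unbalanced data raise rather than silently choosing a
    sum-of-squares type.
    """
    cells: dict[tuple[str, str], list[float]] = {}
    for r in records:
        cells.setdefault((r.patient_id, r.treatment), []).append(r.delta_isc)
    patients = sorted({p for p, _ in cells})
    treatments = sorted({t for _, t in cells})
    a, b = len(treatments), len(patients)
    if b < 2 or a < 2:
        raise ArgumentError("two-way ANOVA needs >= 2 patients and >= 2 treatments")
    sizes = set()
    for p in patients:
        for t in treatments:
            if (p, t) not in cells:
                raise ArgumentError(
                    f"unbalanced design: patient {p!r} is missing treatment {t!r}"
                )
            sizes.add(len(cells[(p, t)]))
    if len(sizes) != 1:
        raise ArgumentError(f"unbalanced design: cell sizes differ ({sorted(sizes)})")
    r_rep = sizes.pop()
    if r_rep < 2:
        raise ArgumentError("two-way ANOVA needs >= 2 replicates per cell")

    data = np.array(
        [[cells[(p, t)] for p in patients] for t in treatments], dtype=float
    )  # shape (a, b, r)
    grand = data.mean()
    t_means = data.mean(axis=(1, 2))
    p_means = data.mean(axis=(0, 2))
    cell_means = data.mean(axis=2)

    ss_t = b * r_rep * float(np.sum((t_means - grand) ** 2))
    ss_p = a * r_rep * float(np.sum((p_means - grand) ** 2))
    ss_cells = r_rep * float(np.sum((cell_means - grand) ** 2))
    ss_int = ss_cells - ss_t - ss_p
    ss_res = float(np.sum((data - cell_means[:, :, None]) ** 2))
    ss_total = ss_t + ss_p + ss_int + ss_res

    if ss_total == 0:
        return TwoWayPartition(0.0, 0.0, 0.0, 0.0, math.nan, degenerate=True)

    df_int = (a - 1) * (b - 1)
    df_res = a * b * (r_rep - 1)
    ms_int = ss_int / df_int
    ms_res = ss_res / df_res
    if ms_res > 0:
        f_int = ms_int / ms_res
        p_int = float(stats.f.sf(f_int, df_int, df_res))
    else:
        p_int = 0.0 if ms_int > 0 else math.nan
    pct = lambda ss: 100.0 * ss / ss_total
    return TwoWayPartition(
        percent_treatment=pct(ss_t),
        percent_patient=pct(ss_p),
        percent_interaction=pct(ss_int),
        percent_residual=pct(ss_res),
        p_interaction=p_int,
        degenerate=ms_res == 0,
    )
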