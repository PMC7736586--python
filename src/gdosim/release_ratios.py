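"""Release isotope ratios and the tracer-to-Gd-148 body-burden scaling factors.

A release scenario is characterised by the activity ratios of the gamma
emitters to Gd-148 in the released tungsten-target material at the moment of
release (t0): a_146/148(t0) and a_153/148(t0).  These depend on target
operation time and are configuration inputs here (they come from target
inventory simulations); the bundled anchors are a 5-year-operated target
(a_146/148 = 21.0, a_153/148 = 13.4) and a 1-year-operated target
(101 and 42.5).

In the environment only radioactive decay is assumed (ecological half-times
equal physical half-lives), so a ratio evolves as the tracer decays while
Gd-148 stays essentially constant.  The k-factor k_148/x(t) converts a
measured whole-body tracer activity into the co-ingested Gd-148 whole-body
activity under chronic intake that started at t0; at t0 it equals
1/a_x/148(t0).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidConfigError, InvalidInputError, UnmeasurableSignalError
from .ingestion_biokinetics import (
    IngestionParams,
    gi_content_chronic,
    systemic_content_chronic,
)
from .nuclide_data import Nuclide, builtin_nuclides, decay_factor

#: Published anchor ratios (operation years -> (a_146/148, a_153/148)).
#: The 5-y a_153/148 is inferred from the corresponding detection-limit
#: table rather than printed directly.
RATIO_ANCHORS: dict[int, tuple[float, float]] = {
    1: (101.0, 42.5),
    5: (21.0, 13.4),
}


@dataclass(frozen=True)
class ReleaseScenario:
    """Initial (t0) activity ratios of the gamma emitters to Gd-148."""

    operation_years: float
    a_146_148_t0: float
    a_153_148_t0: float

    def __post_init__(self) -> None:
        if self.a_146_148_t0 <= 0 or self.a_153_148_t0 <= 0:
            raise InvalidConfigError("activity ratios must be > 0")

    @classmethod
    def five_year(cls) -> "ReleaseScenario":
        return cls(5.0, *RATIO_ANCHORS[5])

    @classmethod
    def one_year(cls) -> "ReleaseScenario":
        return cls(1.0, *RATIO_ANCHORS[1])

    @classmethod
    def from_operation_years(cls, years: int) -> "ReleaseScenario":
        try:
            a146, a153 = RATIO_ANCHORS[years]
        except KeyError:
            raise InvalidConfigError(
                f"no bundled ratio anchor for {years} y operation; "
                f"available: {sorted(RATIO_ANCHORS)}"
            ) from None
        return cls(float(years), a146, a153)

    def initial_ratio(self, tracer: Nuclide) -> float:
        if tracer.name == "Gd-146":
            return self.a_146_148_t0
        if tracer.name == "Gd-153":
            return self.a_153_148_t0
        raise InvalidInputError(f"{tracer.name} is not a supported tracer")


def ratio_at_time(
    scenario: ReleaseScenario,
    tracer: Nuclide,
    t: float,
    *,
    gd148: Nuclide | None = None,
) -> float:
    """Environmental activity ratio a_x/148(t) at ``t`` days post release."""
    if t < 0:
        raise InvalidInputError(f"time must be >= 0, got {t}")
    gd148 = gd148 or builtin_nuclides()["Gd-148"]
    return scenario.initial_ratio(tracer) * decay_factor(tracer, t) / decay_factor(gd148, t)


def tracer_body_burden(
    scenario: ReleaseScenario,
    tracer: Nuclide,
    t: float,
    params: IngestionParams = IngestionParams(),
    *,
    gi_only: bool = False,
) -> float:
    """Whole-body tracer activity (Bq) per unit Gd-148 daily intake at t0.

    The tracer daily intake starts at a_x/148(t0) Bq/day and decays with the
    tracer's physical half-life in the environment.
    """
    a0 = scenario.initial_ratio(tracer)
    gi = gi_content_chronic(a0, t, tracer, params, environmental_decay=True)
    if gi_only:
        return gi
    return gi + systemic_content_chronic(a0, t, tracer, params, environmental_decay=True)


def gd148_body_burden(
    t: float,
    params: IngestionParams = IngestionParams(),
    *,
    gd148: Nuclide | None = None,
    gi_only: bool = False,
) -> float:
    """Whole-body Gd-148 activity (Bq) per unit daily intake at t0."""
    gd148 = gd148 or builtin_nuclides()["Gd-148"]
    gi = gi_content_chronic(1.0, t, gd148, params, environmental_decay=True)
    if gi_only:
        return gi
    return gi + systemic_content_chronic(1.0, t, gd148, params, environmental_decay=True)


def k_factor(
    scenario: ReleaseScenario,
    tracer: Nuclide,
    t: float,
    params: IngestionParams = IngestionParams(),
    *,
    gd148: Nuclide | None = None,
    gi_only: bool = False,
    floor: float = 1e-12,
) -> float:
    """Bq of whole-body Gd-148 per Bq of whole-body tracer at ``t`` days.

    Computed from the full (GI + systemic) chronic-ingestion burdens of both
    isotopes; ``gi_only=True`` selects the GI-dominated approximation for
    cross-checks.  k(t0) = 1/a_x/148(t0) exactly.
    """
    if t < 0:
        raise InvalidInputError(f"time must be >= 0, got {t}")
    if t == 0.0:
        # limit of the burden ratio: both burdens ~ intake_rate * t
        return 1.0 / scenario.initial_ratio(tracer)
    q_tracer = tracer_body_burden(scenario, tracer, t, params, gi_only=gi_only)
    if q_tracer < floor:
        raise UnmeasurableSignalError(
            f"tracer burden {q_tracer:.3e} Bq below floor {floor:.0e} at t={t} d"
        )
    return gd148_body_burden(t, params, gd148=gd148, gi_only=gi_only) / q_tracer
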