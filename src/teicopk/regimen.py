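"""Dosing regimen specification and expansion into dose events.

A regimen is a loading phase (typically q12h x 4) followed by a maintenance
phase (q24h x 5 or q12h x 10). Doses may be expressed per kilogram of body
weight (the usual clinical prescription) or as absolute milligram amounts
after resolution against a subject's weight.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class DoseEvent:
    """A single zero-order infusion: start time (h), amount, duration (h).

    ``amount`` is mg/kg for a per-kg regimen and mg for a resolved one.
    """

    time: float
    amount: float
    duration: float

    @property
    def rate(self) -> float:
        return self.amount / self.duration


@dataclass(frozen=True)
class Regimen:
    """Loading + maintenance dosing schedule with zero-order infusions.

    Parameters
    ----------
    ld_dose, md_dose
        Loading / maintenance dose per event (mg/kg if ``per_kg``, else mg).
    ld_interval, md_interval
        Dosing intervals in hours.
    ld_count, md_count
        Number of loading and maintenance doses. Maintenance dosing starts
        one loading interval after the last loading dose, i.e. at
        ``ld_count * ld_interval`` hours.
    infusion_duration
        Length of each zero-order infusion in hours (default 0.5 h).
    """

    ld_dose: float
    md_dose: float
    ld_interval: float = 12.0
    ld_count: int = 4
    md_interval: float = 24.0
    md_count: int = 5
    infusion_duration: float = 0.5
    per_kg: bool = True

    def __post_init__(self) -> None:
        if self.ld_interval <= 0 or self.md_interval <= 0:
            raise ValueError("dosing intervals must be positive")
        if self.ld_count < 0 or self.md_count < 0:
            raise ValueError("dose counts must be nonnegative")
        if self.ld_dose < 0 or self.md_dose < 0:
            raise ValueError("doses must be nonnegative")
        if self.infusion_duration <= 0:
            raise ValueError("infusion duration must be positive")
        # back-to-back infusions are fine; an infusion longer than its own
        # interval would overlap the next dose of the same phase
        if self.ld_count > 1 and self.infusion_duration > self.ld_interval:
            raise ValueError("infusion duration exceeds loading interval")
        if self.md_count > 1 and self.infusion_duration > self.md_interval:
            raise ValueError("infusion duration exceeds maintenance interval")

    @property
    def md_start(self) -> float:
        """Start time of the maintenance phase (h)."""
        return self.ld_count * self.ld_interval

    def events(self) -> list[DoseEvent]:
        return build_regimen(self)

    def resolved(self, weight_kg: float) -> "Regimen":
        """Convert a per-kg regimen to absolute mg doses for one subject."""
        if not self.per_kg:
            raise ValueError("regimen is already resolved to absolute doses")
        if weight_kg <= 0:
            raise ValueError("weight must be positive")
        return replace(
            self,
            ld_dose=self.ld_dose * weight_kg,
            md_dose=self.md_dose * weight_kg,
            per_kg=False,
        )


def build_regimen(spec: Regimen) -> list[DoseEvent]:
    """Expand a :class:`Regimen` into its ordered dose events.

    Loading doses are placed at ``0, ld_interval, ...``; maintenance doses
    start at ``ld_count * ld_interval`` and continue every ``md_interval``.
    For the default schedules this gives loading doses at 0/12/24/36 h and
    maintenance doses at 48, 72, ... h (q24h) or 48, 60, ... h (q12h).
    """
    events = [
        DoseEvent(i * spec.ld_interval, spec.ld_dose, spec.infusion_duration)
        for i in range(spec.ld_count)
    ]
    start = spec.md_start
    events += [
        DoseEvent(start + i * spec.md_interval, spec.md_dose, spec.infusion_duration)
        for i in range(spec.md_count)
    ]
    return events
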