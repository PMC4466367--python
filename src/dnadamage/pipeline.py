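"""End-to-end orchestration: generation -> location -> scoring -> statistics."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .events import ELECTRON, EventSet, GeneratorConfig, generate
from .geometry import (
    ConformationModel,
    ROIParams,
    build_conformation,
    predicted_hit_probability,
)
from .locator import hit_mask, locate_points
from .scoring import (
    DSB_MAX_SEPARATION_BP,
    SSB_THRESHOLD_EV,
    compute_yields,
    ssb_records_from_arrays,
    tally_damage,
)
from .stats import RunStats, absorbed_dose, electron_fractions, site_hit_probability, site_hit_sem

__all__ = ["RunConfig", "run_single", "run_experiment"]


class RunConfigError(ValueError):
    """An experiment configuration field is invalid."""


@dataclass(frozen=True)
class RunConfig:
    """One experiment: conformations x seeds under a common generator setup."""

    conformations: Sequence[str] = ("A", "B", "Z")
    seeds: Sequence[int] = (0,)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    roi: ROIParams = field(default_factory=ROIParams)
    ssb_threshold: float = SSB_THRESHOLD_EV
    dsb_max_separation: int = DSB_MAX_SEPARATION_BP
    out: str | Path | None = None

    def validate(self) -> None:
        for label in self.conformations:
            if label not in ("A", "B", "Z"):
                raise RunConfigError(f"conformations: unknown label {label!r}")
        if not self.seeds:
            raise RunConfigError("seeds: need at least one seed")
        if self.ssb_threshold < 0:
            raise RunConfigError("ssb_threshold: must be non-negative")
        if self.dsb_max_separation < 0:
            raise RunConfigError("dsb_max_separation: must be non-negative")
        try:
            self.generator.validate()
        except ValueError as exc:
            raise RunConfigError(f"generator: {exc}") from exc


def run_single(
    model: ConformationModel,
    events: EventSet,
    ssb_threshold: float = SSB_THRESHOLD_EV,
    dsb_max_separation: int = DSB_MAX_SEPARATION_BP,
) -> dict:
    """Score one event set against one conformation model."""
    roi = model.roi
    located = locate_points(events.positions, model)
    hits = hit_mask(located)
    ssbs = ssb_records_from_arrays(
        located, events.energies, events.histories, threshold=ssb_threshold
    )
    tally = tally_damage(ssbs, max_sep=dsb_max_separation)
    dose = absorbed_dose(events, roi)
    f_ev, f_dose = electron_fractions(events, roi)
    per_history = events.config is not None and events.config.mode == "track"
    stats = RunStats(
        dose=dose,
        n_events=events.n_events,
        n_events_electron=int(np.sum(events.particles == ELECTRON)),
        electron_event_fraction=f_ev,
        electron_dose_fraction=f_dose,
        site_hit_probability=site_hit_probability(tally.n_tsb, events.n_events),
        site_hit_sem=site_hit_sem(
            hits, histories=events.histories if per_history else None
        ),
    )
    yields = compute_yields(tally, dose, model.total_bp) if dose > 0 else None
    cfg = events.config
    return {
        "conformation": model.label,
        "seed": cfg.seed if cfg else None,
        "mode": cfg.mode if cfg else "file",
        "let_kev_um": cfg.let if cfg and cfg.mode == "track" else float("nan"),
        "dose_gy": dose,
        "n_histories": events.n_histories,
        "n_events": events.n_events,
        "n_events_electron": stats.n_events_electron,
        "electron_event_fraction": stats.electron_event_fraction,
        "electron_dose_fraction": stats.electron_dose_fraction,
        "n_ssb": tally.n_ssb_simple,
        "n_dsb": tally.n_dsb,
        "n_tsb": tally.n_tsb,
        "site_hit_probability": stats.site_hit_probability,
        "site_hit_sem": stats.site_hit_sem,
        "predicted_hit_probability": predicted_hit_probability(model),
        "yield_ssb_per_bp_gy": yields.ssb if yields else float("nan"),
        "yield_dsb_per_bp_gy": yields.dsb if yields else float("nan"),
        "yield_tsb_per_bp_gy": yields.tsb if yields else float("nan"),
    }


def run_experiment(config: RunConfig) -> pd.DataFrame:
    """One results row per (conformation, seed); deterministic given seeds."""
    config.validate()
    rows = []
    for label in config.conformations:
        model = build_conformation(label, config.roi)
        for seed in config.seeds:
            gen = replace(config.generator, seed=int(seed))
            events = generate(gen, config.roi)
            rows.append(
                run_single(
                    model,
                    events,
                    ssb_threshold=config.ssb_threshold,
                    dsb_max_separation=config.dsb_max_separation,
                )
            )
    frame = pd.DataFrame(rows)
    if config.out is not None:
        frame.to_csv(config.out, index=False)
    return frame
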