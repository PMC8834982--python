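"""End-to-end orchestration: synthesize → screen → verify → classify → report.

The pipeline mirrors the workflow shape of a gating study on synthetic
data: a batch of channel conformers (some constructed with an occluded
pore) is triaged by a fast short-run conductance screen, the survivors are
re-simulated for longer to verify a stable low conductance, each verified
trajectory is classified into a conducting regime, and a report table of
conductances and current ratios is assembled. Everything is deterministic
given the config seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, permeation, regimes, structmet, synth
from .specs import ChannelSpec, ToyEnsembleSpec, ValidationError, channel_spec_from_dict


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    ``n_channels`` conformers are synthesized, of which the first
    ``n_obstructed`` carry an obstructed pore (fraction
    ``obstruction_fraction``). Durations are in ns; thresholds in nS.
    """

    channel: ChannelSpec = field(default_factory=ChannelSpec)
    n_channels: int = 24
    n_obstructed: int = 7
    obstruction_fraction: float = 0.8
    screen_duration: float = 250.0
    verify_duration: float = 400.0
    dt: float = 0.005
    seed: int = 0
    thresholds: dict = field(
        default_factory=lambda: {
            "screen_nS": 2.5,
            "sigma_nS": 2.3,
            "r2": 0.99,
            "band": [0.40, 0.60],
        }
    )
    renorm: float = 1.0
    gate_halfwidth: float = 10.0
    min_segment: float = 25.0
    toy_frames: int = 30

    def validate(self) -> None:
        self.channel.validate()
        if not 0 <= self.n_obstructed <= self.n_channels:
            raise ValidationError("need 0 <= n_obstructed <= n_channels")
        if min(self.screen_duration, self.verify_duration, self.dt) <= 0:
            raise ValidationError("durations and dt must be > 0")
        band = self.thresholds.get("band", [0.4, 0.6])
        if not (band[0] < band[1]):
            raise ValidationError("band must be ordered")
        for key in ("screen_nS", "sigma_nS", "r2"):
            if self.thresholds.get(key, 1) <= 0:
                raise ValidationError(f"threshold {key} must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        if "channel" in raw:
            raw["channel"] = channel_spec_from_dict(raw["channel"])
        return cls(**raw)

    def to_canonical_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_canonical_json().encode()).hexdigest()[:16]


def _conductance_of_run(
    spec: ChannelSpec, duration: float, cfg: PipelineConfig, seed: int
):
    n = spec.matched_ion_count()
    traj = synth.simulate_pore_bd(spec, duration, cfg.dt, n, seed)
    events = permeation.detect_crossings(
        traj, cfg.gate_halfwidth, pore_radius=spec.pore_radius
    )
    series = permeation.cumulative_charge(events, traj.times)
    est = permeation.estimate_current(series, spec.voltage, renorm=cfg.renorm)
    return est, series


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the report dict (JSON-serializable).

    A stage failure is recorded in the report (status "failed" with the
    error message) and downstream stages are skipped; the partial report is
    still returned.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = ss.generate_state(4 * config.n_channels + 8) % (2**31)
    report: dict = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
        },
        "stages": {},
        "table": [],
    }

    open_ref = synth.analytic_pore_conductance(
        dataclasses.replace(config.channel, obstruction_fraction=0.0)
    )
    thresholds = config.thresholds

    # -- stage 1: synthesize the conformer batch ---------------------------
    channels = []
    for i in range(config.n_channels):
        f = config.obstruction_fraction if i < config.n_obstructed else 0.0
        channels.append(
            dataclasses.replace(config.channel, obstruction_fraction=f)
        )
    report["stages"]["synthesize"] = {
        "status": "ok",
        "n_channels": config.n_channels,
        "n_obstructed_constructed": config.n_obstructed,
        "open_reference_nS": round(open_ref, 3),
    }

    # -- stage 2: fast conductance screening -------------------------------
    try:
        screen_estimates = []
        for i, spec in enumerate(channels):
            est, _ = _conductance_of_run(
                spec, config.screen_duration, config, int(stage_seeds[i])
            )
            screen_estimates.append(est)
        selected, summary = regimes.screen_conformers(
            screen_estimates,
            threshold_ns=thresholds["screen_nS"],
            open_reference_ns=open_ref,
        )
        selected_idx = [
            i for i, e in enumerate(screen_estimates)
            if e.conductance < thresholds["screen_nS"]
        ]
        report["stages"]["screen"] = {"status": "ok", **summary}
    except Exception as exc:  # noqa: BLE001
        report["stages"]["screen"] = {"status": "failed", "error": str(exc)}
        return report

    # -- stage 3: long-run verification ------------------------------------
    try:
        verified = []
        for j, idx in enumerate(selected_idx):
            est, series = _conductance_of_run(
                channels[idx],
                config.verify_duration,
                config,
                int(stage_seeds[config.n_channels + idx]),
            )
            verified.append((idx, est, series))
        report["stages"]["verify"] = {
            "status": "ok",
            "n_verified": len(verified),
            "duration_ns": config.verify_duration,
        }
    except Exception as exc:  # noqa: BLE001
        report["stages"]["verify"] = {"status": "failed", "error": str(exc)}
        return report

    # -- stage 4: regime classification ------------------------------------
    try:
        classified = []
        for idx, est, series in verified:
            single = regimes.fit_single(series, config.channel.voltage, config.renorm)
            try:
                two = regimes.fit_changepoint(
                    series, config.min_segment, config.channel.voltage, config.renorm
                )
                best = regimes.select_model(single, two)
            except ValidationError:
                best = single
            state = regimes.classify_state(
                best,
                open_reference_ns=open_ref,
                sigma_threshold=thresholds["sigma_nS"],
                r2_threshold=thresholds["r2"],
                band=tuple(thresholds["band"]),
            )
            classified.append((idx, est, best, state))
            report["table"].append(
                {
                    "trajectory": f"channel-{idx:03d}",
                    "conductance_nS": round(est.conductance, 2),
                    "current_ratio": (
                        round(est.current_ratio, 1)
                        if np.isfinite(est.current_ratio)
                        else None
                    ),
                    "model": best.model,
                    "bifurcation_time_ns": best.bifurcation_time,
                    "state": state.label,
                    "sigma_nS": round(state.sigma, 3),
                    "fraction_of_open": round(state.fraction_of_open, 2),
                }
            )
        report["stages"]["classify"] = {
            "status": "ok",
            "labels": {
                lab: sum(1 for *_x, s in classified if s.label == lab)
                for lab in {s.label for *_x, s in classified}
            },
        }
    except Exception as exc:  # noqa: BLE001
        report["stages"]["classify"] = {"status": "failed", "error": str(exc)}
        return report

    # -- stage 5: structural metrics on toy ensembles ----------------------
    try:
        toy_specs = {
            "occluded": ToyEnsembleSpec(
                n_frames=config.toy_frames,
                tail_placement="horizontal-mid-pore",
                seed=int(stage_seeds[-2]),
            ),
            "open": ToyEnsembleSpec(
                n_frames=config.toy_frames,
                tail_placement="vertical",
                seed=int(stage_seeds[-1]),
            ),
        }
        ensembles = {k: synth.make_toy_ensemble(s) for k, s in toy_specs.items()}
        ell = {
            k: float(np.mean(structmet.ellipticity_series(e)))
            for k, e in ensembles.items()
        }
        model = structmet.pca_landscape(
            [e for e in ensembles.values()],
            selection=list(ensembles.values())[0].select(segment="tail"),
        )
        overlap, _mask = structmet.ensemble_overlap(
            model, "horizontal-mid-pore", "vertical"
        )
        report["stages"]["structure"] = {
            "status": "ok",
            "mean_ellipticity": {k: round(v, 3) for k, v in ell.items()},
            "pc_overlap_fraction": round(overlap, 3),
        }
    except Exception as exc:  # noqa: BLE001
        report["stages"]["structure"] = {"status": "failed", "error": str(exc)}
        return report

    return report


def verify_report(report: dict) -> list[str]:
    """Re-derive report arithmetic from stage artifacts; returns differences.

    Checks that the screening counts are consistent and that every table
    row's derived quantities are internally coherent (fraction_of_open =
    conductance / open reference at the rounding precision).
    """
    problems = []
    stages = report.get("stages", {})
    screen = stages.get("screen", {})
    if screen.get("status") == "ok":
        if screen["n_selected"] > screen["n_total"]:
            problems.append("screen: selected exceeds total")
        expect_pct = int(
            100.0 * screen["threshold_nS"] / screen["open_reference_nS"]
        )
        if expect_pct != screen["threshold_percent_of_open"]:
            problems.append("screen: threshold percentage mismatch")
    open_ref = stages.get("synthesize", {}).get("open_reference_nS")
    if open_ref:
        for row in report.get("table", []):
            frac = row["sigma_nS"] / open_ref
            if abs(frac - row["fraction_of_open"]) > 0.02:
                problems.append(
                    f"{row['trajectory']}: fraction_of_open inconsistent"
                )
    return problems


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
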