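"""End-to-end orchestration: simulate → detect → localize → classify → estimate.

The pipeline runs a synthetic survey with known truth through the whole
analysis chain and writes the CSV interfaces of every stage plus an
event "funnel" table (detected → localized → converged → truncated →
3D-localized) and a structured run log. All thresholds of the analysis
surface as named config keys with their survey defaults (12 dB trigger,
0.02 correlation threshold, 0.0005–0.015 s delay window, 6500 m event
truncation, 4000 m click-depth truncation, 5 min / 800 m / 1600 m dive
splits, 400 m depth bins, Q1 assumed-depth rule).
"""

from __future__ import annotations

import dataclasses
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import distance as dist
from . import dive as dive_mod
from . import localize as loc
from . import signal as sig
from . import simulate as sim

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "validate_config",
    "run_pipeline",
    "summarize_effort",
    "silence_window",
]

log = logging.getLogger("cachalot")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "effort_length_km": 150.0,
        "vessel_speed_kmh": 18.0,
        "array_depth_m": 7.5,
        "array_setback_m": 300.0,
        "pair_spacing_m": 0.25,
        "sound_speed_ms": 1500.0,
        "whale_density_per_km2": 0.02,
        "truncation_m": 6500.0,
        "noise_snr_db": 30.0,
        "snr_reference_range_m": 2000.0,
        "sample_rate_hz": 96000,
        "max_clips_per_event": 64,
        "bathymetry": {"kind": "flat", "depth_m": 2500.0},
        "bearing_noise_deg": 1.0,
        "echo_amplitude": 0.3,
        "write_wav": False,
    },
    "signal": {
        "threshold_db": 12.0,
        "correlation_threshold": 0.02,
        "delay_window_s": [0.0005, 0.015],
        "qc_window": 11,
        "qc_k": 3.0,
        "min_clicks": 8,
    },
    "localize": {
        "truncation_m": 6500.0,
        "max_click_depth_m": 4000.0,
    },
    "dive": {
        "bin_m": 400.0,
        "max_gap_s": 120.0,
    },
    "distance": {
        "assumed_depth_rule": "Q1",
        "w": 6500.0,
        "n_boot": 99,
        "gof_models": "best",
        "n_legs": 10,
    },
    "stages": {
        "detect": True,
        "localize": True,
        "depth": True,
        "classify": True,
        "estimate": True,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, value in override.items():
        if key not in base:
            raise KeyError(f"unknown config key: {path}{key}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise TypeError(f"config section {path}{key} must be a mapping")
            out[key] = _merge(base[key], value, f"{path}{key}.")
        else:
            out[key] = value
    return out


def validate_config(config: dict | None) -> dict:
    """Merge onto the defaults, rejecting unknown keys."""
    return _merge(DEFAULT_CONFIG, config or {})


def load_config(path) -> dict:
    """Read a YAML run config and validate it against the defaults."""
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def silence_window(vessel_speed_kmh: float, detection_range_km: float) -> float:
    """Minutes a whale must stay silent to be missed entirely.

    The vessel traverses the detection window (twice the effective
    detection range) in ``60 × 2·range / speed`` minutes; a whale silent
    for longer than this between dives could go undetected.
    """
    if vessel_speed_kmh <= 0:
        raise ValueError("vessel speed must be positive")
    if detection_range_km < 0:
        raise ValueError("detection range must be non-negative")
    return 60.0 * (2.0 * detection_range_km) / vessel_speed_kmh


def summarize_effort(
    detections,
    effort_legs: pd.DataFrame,
    grouping: str = "group",
) -> pd.DataFrame:
    """Per-group effort and detection-rate summary.

    ``effort_legs`` has one row per group with columns ``km`` and
    optionally ``hours`` and ``days``; ``detections`` is either a
    DataFrame with a ``grouping`` column (one row per detection) or a
    mapping group → count. Rates are recomputed from counts and
    denominators — never stored independently — and the ``percent_km``
    column is each group's share of total effort.
    """
    legs = effort_legs.set_index(grouping) if grouping in effort_legs else effort_legs
    if np.any(legs["km"] <= 0):
        raise ValueError("effort legs must have positive lengths")
    if isinstance(detections, pd.DataFrame):
        counts = detections.groupby(grouping).size().astype(float)
    else:
        counts = pd.Series(dict(detections), dtype=float)
    out = legs.copy()
    out["detections"] = counts.reindex(out.index).fillna(0).astype(int)
    total_km = float(out["km"].sum())
    out["percent_km"] = 100.0 * out["km"] / total_km
    out["detections_per_km"] = out["detections"] / out["km"]
    if "hours" in out:
        with np.errstate(divide="ignore"):
            out["detections_per_hour"] = np.where(
                out["hours"] > 0, out["detections"] / out["hours"], np.nan
            )
    return out.reset_index()


# ---------------------------------------------------------------------------
# the synthetic end-to-end run


def _clamp_to_grid(loc2d, bathy: sim.BathymetryGrid) -> tuple[float, float]:
    """Nearest in-grid position for the seafloor lookup of a TMA solution."""
    ny, nx = bathy.depths_m.shape
    x0, y0 = bathy.origin_xy
    eps = 0.5 * bathy.cell_size_m
    x = float(np.clip(loc2d.x_m, x0 + eps, x0 + nx * bathy.cell_size_m - eps))
    y = float(np.clip(loc2d.y_m, y0 + eps, y0 + ny * bathy.cell_size_m - eps))
    return x, y


def _event_audio_measurements(whale, click_t, hx, cfg, rng):
    """Synthesize clips for one event's clicks and measure slant delays.

    The per-click SNR falls off with range by spherical spreading
    relative to ``snr_reference_range_m``, so distant whales produce
    weak clips whose echoes fail the correlation threshold — the same
    selection that operates on real recordings.
    """
    simc = cfg["simulate"]
    sigc = cfg["signal"]
    h = simc["array_depth_m"]
    c = simc["sound_speed_ms"]
    ref = simc["snr_reference_range_m"]
    measurements = []
    for t, x_h in zip(click_t, hx):
        wpos = np.array([whale.x_m, whale.perpendicular_distance_m, whale.depth_at(t)])
        hpos = np.array([x_h, 0.0, h])
        direct, echo_delay, _ = sim.propagate_click(
            wpos, hpos, c, simc["pair_spacing_m"]
        )
        range_m = float(direct) * c
        snr = simc["noise_snr_db"] - 20.0 * np.log10(max(range_m, ref) / ref)
        clip, _ = sim.synthesize_clip(
            0.0,
            float(echo_delay),
            snr_db=snr,
            fs=simc["sample_rate_hz"],
            seed=rng,
            echo_amplitude=simc["echo_amplitude"],
        )
        audio = sig.bandpass_decimate(clip, simc["sample_rate_hz"])
        m = sig.measure_slant_delay(
            sig.ClickClip(audio, sig.TARGET_FS, click_time_s=float(t), event_id=whale.id),
            window_s=tuple(sigc["delay_window_s"]),
            threshold=sigc["correlation_threshold"],
        )
        measurements.append(m)
    return measurements


def run_pipeline(config: dict | None = None, outdir=None) -> dict:
    """Run the synthetic survey pipeline; returns the results bundle.

    The bundle maps table names to DataFrames (``events``, ``funnel``,
    ``depth_summaries``, ``classifications``, ``model_comparison``,
    ``abundance``) plus the scenario truth. Deterministic for a fixed
    config seed. When ``outdir`` is given every table is written as CSV
    alongside a plain-text run log.
    """
    cfg = validate_config(config)
    t_start = time.time()
    rng = np.random.default_rng(cfg["seed"])
    simc = cfg["simulate"]
    stages = cfg["stages"]
    log_lines: list[str] = [f"seed={cfg['seed']}"]

    sc = sim.SimConfig(
        effort_length_km=simc["effort_length_km"],
        vessel_speed_kmh=simc["vessel_speed_kmh"],
        array_depth_m=simc["array_depth_m"],
        array_setback_m=simc["array_setback_m"],
        pair_spacing_m=simc["pair_spacing_m"],
        sound_speed_ms=simc["sound_speed_ms"],
        whale_density_per_km2=simc["whale_density_per_km2"],
        truncation_m=simc["truncation_m"],
        noise_snr_db=simc["noise_snr_db"],
        sample_rate_hz=simc["sample_rate_hz"],
        seed=cfg["seed"],
    )
    bathy_cfg = simc["bathymetry"]
    L_m = sc.effort_length_km * 1000.0
    bathy = sim.make_bathymetry(
        bathy_cfg.get("kind", "flat"),
        x_extent_m=(-30_000.0, L_m + 30_000.0),
        y_extent_m=(-sc.truncation_m - 10_000.0, sc.truncation_m + 10_000.0),
        depth_m=bathy_cfg.get("depth_m", 2500.0),
    )
    whales = sim.place_whales(sc, bathymetry=bathy)
    log_lines.append(f"simulated {len(whales)} whales over {sc.effort_length_km} km")

    v_ms = sc.vessel_speed_kmh / 3.6
    c = sc.sound_speed_ms
    h = sc.array_depth_m
    bearing_noise = np.deg2rad(simc["bearing_noise_deg"])
    max_clips = int(simc["max_clips_per_event"])
    sigc = cfg["signal"]

    events: list[dict] = []
    depth_rows: list[dict] = []
    class_rows: list[dict] = []
    rejections: list[dict] = []

    for whale in whales:
        clicks = whale.click_times_s + whale.dive_start_s
        clicks = clicks[(clicks >= 0)]
        if clicks.size == 0:
            continue
        hx = v_ms * clicks - sc.array_setback_m
        row = {
            "event_id": whale.id,
            "n_clicks": int(clicks.size),
            "truth_y_m": whale.perpendicular_distance_m,
            "truth_max_depth_m": whale.max_depth_m,
            "detected": True,
        }

        # subsample clicks for the audio / bearing stages
        if clicks.size > max_clips:
            pick = np.linspace(0, clicks.size - 1, max_clips).round().astype(int)
        else:
            pick = np.arange(clicks.size)
        ct, chx = clicks[pick], hx[pick]

        loc2d = None
        if stages["localize"]:
            wpos = np.column_stack(
                [
                    np.full(ct.size, whale.x_m),
                    np.full(ct.size, whale.perpendicular_distance_m),
                    whale.depth_at(ct),
                ]
            )
            hpos = np.column_stack([chx, np.zeros(ct.size), np.full(ct.size, h)])
            _, _, dt_pair = sim.propagate_click(wpos, hpos, c, sc.pair_spacing_m)
            with np.errstate(invalid="ignore"):
                theta = loc.bearing_from_delay(dt_pair, sc.pair_spacing_m, c)
            theta = np.clip(theta + rng.normal(0, bearing_noise, ct.size), 0, np.pi)
            try:
                loc2d = loc.tma_simplex(
                    loc.BearingSeries(ct, theta, chx, h), seed=int(rng.integers(2**31))
                )
                row["localized"] = True
                row["converged"] = loc2d.converged
                row["slant_range_m"] = loc2d.slant_range_m
                row["range_error_m"] = loc2d.error_m
                row["x_m"] = loc2d.x_m
            except ValueError as err:
                row["localized"] = False
                row["converged"] = False
                rejections.append({"event_id": whale.id, "stage": "tma", "reason": str(err)})
        events.append(row)
        if loc2d is None or not loc2d.converged:
            if loc2d is not None:
                rejections.append(
                    {"event_id": whale.id, "stage": "tma", "reason": "no_convergence"}
                )
            continue
        if loc2d.slant_range_m > cfg["localize"]["truncation_m"]:
            row["truncated"] = True
            rejections.append(
                {"event_id": whale.id, "stage": "truncation", "reason": "slant_gt_w"}
            )
            continue
        row["truncated"] = False

        if not (stages["detect"] and stages["depth"]):
            continue
        measurements = _event_audio_measurements(whale, ct, chx, cfg, rng)
        measurements, event_ok = sig.qc_slant_delays(
            measurements,
            window=sigc["qc_window"],
            k=sigc["qc_k"],
            min_clicks=sigc["min_clicks"],
        )
        if not event_ok:
            rejections.append(
                {"event_id": whale.id, "stage": "slant_delay", "reason": "too_few_clicks"}
            )
            continue
        acc = [m for m in measurements if m.accepted]
        radial = np.hypot(
            loc2d.x_m - (v_ms * np.array([m.click_time_s for m in acc]) - sc.array_setback_m),
            loc2d.slant_range_m,
        )
        cds = [
            loc.click_depth(m.tau_s, float(D), h, c, sd_tau_s=1.0 / sig.TARGET_FS,
                            sd_D_m=loc2d.error_m)
            for m, D in zip(acc, radial)
        ]
        kept = [cd for cd in cds if not cd.truncated]
        if len(kept) < sigc["min_clicks"]:
            rejections.append(
                {"event_id": whale.id, "stage": "depth", "reason": "too_few_clicks"}
            )
            continue
        summary = loc.event_depth_summary(cds, min_clicks=sigc["min_clicks"])
        summary = loc.reject_by_seafloor(summary, _clamp_to_grid(loc2d, bathy), bathy)
        if not summary.accepted:
            rejections.append(
                {
                    "event_id": whale.id,
                    "stage": "depth",
                    "reason": summary.rejection_reason.value,
                }
            )
        depth_rows.append(
            {
                "event_id": whale.id,
                "n": summary.n_clicks_with_tau,
                "avg_depth_m": summary.average_depth_m,
                "sd_m": summary.sd_m,
                "accepted": summary.accepted,
                "reason": summary.rejection_reason.value,
                # truth over the clicks actually contributing to the estimate
                "truth_depth_mean_m": float(
                    np.mean(
                        [
                            whale.depth_at(m.click_time_s)
                            for m, cd in zip(acc, cds)
                            if not cd.truncated
                        ]
                    )
                ),
            }
        )
        row["depth_accepted"] = summary.accepted

        if stages["classify"] and summary.accepted:
            z_clicks = np.array([cd.z_m for cd in kept])
            t_clicks = np.array(
                [m.click_time_s for m, cd in zip(acc, cds) if not cd.truncated]
            )
            cls = dive_mod.classify_dive(z_clicks, t_clicks)
            profile = dive_mod.bin_time_at_depth(
                z_clicks, t_clicks, bin_m=cfg["dive"]["bin_m"],
                max_gap_s=cfg["dive"]["max_gap_s"],
            )
            class_rows.append(
                {
                    "event_id": whale.id,
                    "pattern": cls.pattern.value,
                    "depth_class": cls.depth_class.value if cls.depth_class else "",
                    "max_depth_m": cls.max_click_depth_m,
                    "duration_min": cls.duration_min,
                    "water_column": dive_mod.seafloor_proximity(
                        z_clicks, bathy.depth_at(*_clamp_to_grid(loc2d, bathy))
                    ),
                }
            )

    events_df = pd.DataFrame(events)
    depth_df = pd.DataFrame(depth_rows)
    class_df = pd.DataFrame(class_rows)
    rej_df = pd.DataFrame(rejections)

    funnel = {
        "detected": len(events_df),
        "localized": int(events_df.get("localized", pd.Series(dtype=bool)).sum()),
        "converged": int(events_df.get("converged", pd.Series(dtype=bool)).sum()),
        "truncated": int((events_df.get("truncated") == False).sum()) if "truncated" in events_df else 0,  # noqa: E712
        "localized_3d": int(depth_df["accepted"].sum()) if len(depth_df) else 0,
    }
    funnel_df = pd.DataFrame([funnel])
    for line in (f"funnel: {funnel}",):
        log_lines.append(line)

    bundle: dict = {
        "config": cfg,
        "events": events_df,
        "funnel": funnel_df,
        "depth_summaries": depth_df,
        "classifications": class_df,
        "rejections": rej_df,
        "truth": pd.DataFrame(
            {
                "event_id": [w.id for w in whales],
                "y_m": [w.perpendicular_distance_m for w in whales],
                "max_depth_m": [w.max_depth_m for w in whales],
                "dive_start_s": [w.dive_start_s for w in whales],
            }
        ),
    }

    if stages["estimate"] and len(events_df) and "truncated" in events_df:
        dcfg = cfg["distance"]
        usable = events_df[events_df.get("truncated") == False]  # noqa: E712
        accepted_depths = (
            depth_df[depth_df["accepted"]] if len(depth_df) else pd.DataFrame()
        )
        if len(accepted_depths):
            assumed = dist.assumed_depth(
                accepted_depths["avg_depth_m"].to_numpy(),
                accepted_depths["n"].to_numpy(),
                rule=dcfg["assumed_depth_rule"],
            )
        else:
            assumed = 0.0
        depth_map = (
            accepted_depths.set_index("event_id")["avg_depth_m"]
            if len(accepted_depths)
            else pd.Series(dtype=float)
        )
        rows = []
        for _, ev in usable.iterrows():
            z = depth_map.get(ev["event_id"], np.nan)
            source = "estimated" if np.isfinite(z) else "assumed"
            z_used = z if np.isfinite(z) else assumed
            rows.append(
                {
                    "event_id": ev["event_id"],
                    "slant_m": ev["slant_range_m"],
                    "depth_m": z_used,
                    "depth_source": source,
                    "corrected_m": dist.correct_distance(ev["slant_range_m"], z_used),
                }
            )
        dist_df = pd.DataFrame(rows)
        bundle["distances"] = dist_df
        if len(dist_df) >= 20:
            fits = dist.fit_model_set(dist_df["corrected_m"].to_numpy(), w=dcfg["w"])
            best = dist.select_model(fits)
            gof_targets = fits if dcfg["gof_models"] == "all" else [best]
            for f in gof_targets:
                dist.gof(f, dist_df["corrected_m"].to_numpy(), n_boot=dcfg["n_boot"],
                         seed=cfg["seed"])
            bundle["model_comparison"] = dist.comparison_table(fits)
            n_legs = int(dcfg["n_legs"])
            edges = np.linspace(0, L_m, n_legs + 1)
            x_ev = usable["x_m"].to_numpy()
            counts = np.histogram(np.clip(x_ev, 0, L_m - 1), bins=edges)[0]
            leg_km = np.diff(edges) / 1000.0
            est = dist.estimate_abundance(
                best,
                n=len(dist_df),
                L_km=sc.effort_length_km,
                A_km2=2.0 * dcfg["w"] / 1000.0 * sc.effort_length_km,
                leg_lengths_km=leg_km,
                leg_counts=counts,
            )
            bundle["abundance"] = pd.DataFrame([dataclasses.asdict(est)])
            log_lines.append(
                f"best model {best.key}/{best.adjustment} ESW={best.esw_:.0f} m "
                f"D={est.density_per_km2:.5f}/km2"
            )
        else:
            log_lines.append("too few distances for a stable detection-function fit")

    elapsed = time.time() - t_start
    log_lines.append(f"elapsed {elapsed:.1f} s")

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in bundle.items():
            if isinstance(df, pd.DataFrame):
                df.to_csv(out / f"{name}.csv", index=False)
        with open(out / "run.log", "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh)
    bundle["log"] = log_lines
    return bundle
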