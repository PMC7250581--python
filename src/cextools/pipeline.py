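"""End-to-end pipeline driver.

A run configuration (YAML or JSON, or a plain dict) selects stages and
their parameters; every parameter that affects results is echoed into a
provenance record next to the outputs. Stages:

* ``simulate`` — synthetic convergence/extension track table (+ movie)
* ``track``   — detect and link nuclei from a TIFF movie
* ``kinematics`` — per-track displacements, gradients, midline crossings
* ``polarity`` — ellipse fits and alignment summaries from cells.csv
* ``protrusions`` — classification + circular histogram from protrusions.csv
* ``pk`` — Prickle-GFP localization scoring from cells.csv + puncta.csv
* ``nucasym`` — nuclear signal asymmetry from DAPI + signal TIFF stacks
* ``morpho`` — explant length/width from shapes.json, neural-plate
  measurements from landmarks.csv

Reruns with the same configuration and seed produce byte-identical CSV
outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
import sys
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io, kinematics, morphometry, nuclear_signal, polarity
from . import synthetic, tracking

logger = logging.getLogger("cextools")


class ConfigError(ValueError):
    """Invalid or unknown configuration keys."""


_KNOWN_TOP = {"stages", "seed", "out_dir", "inputs", "params"}
_KNOWN_STAGES = {
    "simulate",
    "track",
    "kinematics",
    "polarity",
    "protrusions",
    "pk",
    "nucasym",
    "morpho",
}
_KNOWN_PARAMS = {
    "simulate": {
        "n_cells", "domain_half_width", "domain_half_height", "conv_rate",
        "ext_rate", "swirl_rate", "noise_sigma", "dt", "n_steps", "render_movie",
        "pixel_size_um", "spot_sigma_um", "amplitude", "noise_sd",
    },
    "track": {"pixel_size_um", "sigma_um", "threshold", "max_disp", "min_track_len", "dt_min"},
    "kinematics": {"midline_x"},
    "polarity": {"eps"},
    "protrusions": {"scheme", "half_width", "bin_width"},
    "pk": {"membrane_dist", "sector_half"},
    "nucasym": {
        "strategy", "percentile", "k_mad", "threshold", "threshold_method",
        "vmin_um3", "vmax_um3",
    },
    "morpho": set(),
}


def load_config(path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    return cfg


def validate_config(cfg: dict) -> dict:
    unknown = set(cfg) - _KNOWN_TOP
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    stages = cfg.get("stages", [])
    bad = set(stages) - _KNOWN_STAGES
    if bad:
        raise ConfigError(f"unknown stages: {sorted(bad)}")
    params = cfg.get("params", {})
    for stage, block in params.items():
        if stage not in _KNOWN_PARAMS:
            raise ConfigError(f"parameters for unknown stage {stage!r}")
        extra = set(block) - _KNOWN_PARAMS[stage]
        if extra:
            raise ConfigError(f"unknown {stage} parameters: {sorted(extra)}")
    return cfg


def run_pipeline(cfg: dict | str | Path, out_dir=None) -> dict:
    """Execute the configured stages; returns a result bundle dict.

    Writes stage outputs plus ``provenance.json`` into the output
    directory.
    """
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    validate_config(cfg)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    inputs = cfg.get("inputs", {})
    params = cfg.get("params", {})
    results: dict = {}
    for stage in cfg.get("stages", []):
        logger.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](out, inputs, params.get(stage, {}), seed, results)
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
    provenance = {
        "version": __version__,
        "seed": seed,
        "stages": list(cfg.get("stages", [])),
        "params": params,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    io.write_json(out / "provenance.json", provenance)
    return results


def _stage_simulate(out, inputs, p, seed, results):
    p = dict(p)
    render = p.pop("render_movie", False)
    movie_kwargs = {
        k: p.pop(k)
        for k in ("pixel_size_um", "spot_sigma_um", "amplitude", "noise_sd")
        if k in p
    }
    config = synthetic.MIBFieldConfig(seed=seed, **p)
    tracks, truth = synthetic.simulate_mib_tracks(config)
    io.write_tracks(out / "tracks.csv", tracks)
    io.write_json(
        out / "tracks_truth.json",
        {
            "ml_displacement_factor": truth.ml_displacement_factor,
            "ap_displacement_factor": truth.ap_displacement_factor,
            "start_positions": truth.start_positions.to_dict(orient="list"),
        },
    )
    results["tracks"] = tracks
    results["tracks_truth"] = truth
    if render:
        movie, origin = synthetic.render_track_movie(tracks, seed=seed, **movie_kwargs)
        io.write_stack(out / "movie.tif", movie, [movie_kwargs.get("pixel_size_um", 1.0)])
        io.write_json(out / "movie_origin.json", {"origin_xy_um": list(origin)})
        results["movie"] = movie
        results["movie_origin"] = origin


def _stage_track(out, inputs, p, seed, results):
    if "movie" in results:
        movie, origin = results["movie"], results["movie_origin"]
        pixel = p.get("pixel_size_um", 1.0)
    else:
        movie, voxel = io.read_stack(inputs["movie"])
        pixel = p.get("pixel_size_um", voxel[-1])
        origin = (0.0, 0.0)
        if "movie_origin" in inputs:
            origin = tuple(io.read_json(inputs["movie_origin"])["origin_xy_um"])
    dets = tracking.detect_nuclei(
        movie, pixel, p.get("sigma_um", 2.0), p.get("threshold", 10.0), origin_xy=origin
    )
    table = tracking.link_tracks(
        dets,
        max_disp=p.get("max_disp", 10.0),
        min_track_len=p.get("min_track_len", 2),
        dt_min=p.get("dt_min", 5.0),
    )
    io.write_tracks(out / "tracks_detected.csv", table)
    results["tracks_detected"] = table


def _stage_kinematics(out, inputs, p, seed, results):
    if "tracks" in results:
        tracks = results["tracks"]
    elif "tracks_detected" in results:
        tracks = results["tracks_detected"]
    else:
        tracks = io.read_tracks(inputs["tracks"])
    summary = kinematics.summarize_kinematics(tracks, midline_x=p.get("midline_x", 0.0))
    summary["displacements"].to_csv(out / "kinematics.csv", index=False)
    io.write_json(
        out / "kinematics_summary.json",
        {
            "ml_gradient": dataclasses.asdict(summary["ml_gradient"]),
            "ap_gradient": dataclasses.asdict(summary["ap_gradient"]),
            "n_midline_crossings": summary["n_midline_crossings"],
        },
    )
    results["kinematics"] = summary


def _stage_polarity(out, inputs, p, seed, results):
    outlines = io.read_cells(inputs["cells"])
    table = polarity.measure_cells(outlines, eps=p.get("eps", polarity.ORIENTATION_EPS))
    table.to_csv(out / "polarity.csv", index=False)
    reliable = table[table.reliable_orientation]
    if len(reliable):
        summ = polarity.summarize_alignment(reliable.alignment_deg)
        io.write_json(
            out / "alignment_summary.json",
            {
                "n": summ["n"],
                "median_deg": summ["median_deg"],
                "fraction_le_20deg": summ["fraction_le_20deg"],
                "n_excluded_round": int(len(table) - len(reliable)),
            },
        )
    results["polarity"] = table


def _stage_protrusions(out, inputs, p, seed, results):
    df = io.read_protrusions(inputs["protrusions"])
    classified = polarity.classify_protrusions(
        df.angle_deg, scheme=p.get("scheme", "quadrant"), half_width=p.get("half_width")
    )
    classified.insert(0, "cell_id", df.cell_id.to_numpy())
    classified.to_csv(out / "protrusions_classified.csv", index=False)
    hist = polarity.protrusion_histogram(df.angle_deg, bin_width=p.get("bin_width", 20.0))
    io.write_json(out / "protrusion_histogram.json", {"bin_counts": hist.tolist()})
    results["protrusions"] = classified


def _stage_pk(out, inputs, p, seed, results):
    outlines = io.read_cells(inputs["cells"])
    puncta = io.read_puncta(inputs["puncta"])
    scores = polarity.score_pk_cells(
        outlines,
        puncta,
        membrane_dist=p.get("membrane_dist", 1.0),
        sector_half=p.get("sector_half", 45.0),
    )
    scores.to_csv(out / "pk_scores.csv", index=False)
    results["pk"] = scores


def _stage_nucasym(out, inputs, p, seed, results):
    dapi, voxel = io.read_stack(inputs["dapi"])
    signal, _ = io.read_stack(inputs["signal"])
    control = None
    if "control_signals" in inputs:
        control = np.asarray(io.read_json(inputs["control_signals"]), dtype=float)
    kwargs = {k: v for k, v in p.items()}
    strategy = kwargs.pop("strategy", "robust_z" if control is None else "control_percentile")
    nuclei, res = nuclear_signal.analyze_explant(
        dapi, signal, voxel, control_signals=control, strategy=strategy, **kwargs
    )
    nuclei.to_csv(out / "nuclei.csv", index=False)
    io.write_json(out / "asymmetry.json", dataclasses.asdict(res))
    results["nucasym"] = res


def _stage_morpho(out, inputs, p, seed, results):
    rows = []
    if "shape" in inputs:
        shape = io.read_shape(inputs["shape"])
        m = morphometry.measure_length_width(shape)
        rows.append(("explant_length_um", m.length_um))
        rows.append(("explant_width_um", m.width_um))
        rows.append(("explant_lw_ratio", m.ratio))
        results["morpho"] = m
    if "landmarks" in inputs:
        lm = io.read_landmarks(inputs["landmarks"])
        width, length = morphometry.measure_neural_plate(lm)
        rows.append(("neural_plate_width_um", width))
        rows.append(("neural_plate_length_um", length))
        results["neural_plate"] = (width, length)
    if not rows:
        raise ConfigError("morpho stage needs 'shape' and/or 'landmarks' inputs")
    import pandas as pd

    pd.DataFrame(rows, columns=["measurement", "value"]).to_csv(
        out / "morphometry.csv", index=False
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "track": _stage_track,
    "kinematics": _stage_kinematics,
    "polarity": _stage_polarity,
    "protrusions": _stage_protrusions,
    "pk": _stage_pk,
    "nucasym": _stage_nucasym,
    "morpho": _stage_morpho,
}


def setup_logging(verbose: bool = False, quiet: bool = False) -> None:
    level = logging.DEBUG if verbose else logging.ERROR if quiet else logging.INFO
    logging.basicConfig(stream=sys.stderr, level=level, format="%(levelname)s %(message)s")
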