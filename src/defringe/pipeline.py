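"""End-to-end pipeline orchestration for the command-line interface.

A single declarative config drives simulate -> defringe -> metrics -> nri
-> classify.  One top-level seed fans out to per-stage seeds (stage name
hashed with CRC32) so each stage is independently reproducible; unknown
config keys are rejected before any computation.
"""

from __future__ import annotations

import json
import logging
import os
import zlib

import numpy as np

from . import __version__
from .io import HSCube, write_cube, write_mask, drop_bands
from .metrics import score_cube
from .notch import HoneycombNotchFilter
from .nri import build_nri_cube, apply_exclusion_mask
from .classify import gmm_fit, gmm_predict, reference_spectrum, correlation_map
from .synth import (HoneycombSpec, SceneSpec, render_honeycomb,
                    make_usaf_scene, make_two_tissue_cube)

log = logging.getLogger("defringe")

_KNOWN_KEYS = {
    "seed", "out_dir", "scene", "honeycomb", "filter", "drop_bands",
    "metrics", "classify",
}
_SCENE_KEYS = {"kind", "shape", "n_bands", "noise_sd", "low_band_noise_sd",
               "intensity_scale", "bar_groups"}
_HONEYCOMB_KEYS = {"pitch", "core_radius", "core_gain", "cladding_gain",
                   "lattice_angle", "jitter", "conserve_flux"}
_FILTER_KEYS = {"design", "tolerance_t", "tolerance_fraction",
                "dc_exclusion_radius", "border_margin", "scale_a",
                "max_fraction", "sigma", "kappa", "b"}
_METRICS_KEYS = {"gamma"}
_CLASSIFY_KEYS = {"mode", "k", "n_reference_pixels", "subsample", "tol",
                  "max_iter"}


def stage_seed(base_seed: int, stage: str) -> int:
    """Per-stage derived seed: CRC32(stage) XOR base, kept below 2**31."""
    return (zlib.crc32(stage.encode()) ^ int(base_seed)) % (2 ** 31)


def validate_config(config: dict) -> dict:
    def check(d, allowed, ctx):
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config key(s) in {ctx}: {sorted(unknown)}")

    check(config, _KNOWN_KEYS, "top level")
    check(config.get("scene", {}), _SCENE_KEYS, "scene")
    check(config.get("honeycomb", {}), _HONEYCOMB_KEYS, "honeycomb")
    check(config.get("filter", {}), _FILTER_KEYS, "filter")
    check(config.get("metrics", {}), _METRICS_KEYS, "metrics")
    check(config.get("classify", {}), _CLASSIFY_KEYS, "classify")
    return config


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the configured stages; returns a summary dict (also written
    as ``summary.json`` in the output directory)."""
    validate_config(config)
    seed = int(config.get("seed", 0))
    out_dir = out_dir or config.get("out_dir", "defringe_out")
    os.makedirs(out_dir, exist_ok=True)
    summary = {"version": __version__, "seed": seed, "config": config}

    scene_cfg = dict(config.get("scene", {}))
    kind = scene_cfg.pop("kind", "two_tissue")
    hc_cfg = dict(config.get("honeycomb", {}))
    hc_spec = HoneycombSpec(seed=stage_seed(seed, "simulate"), **hc_cfg)

    regions = None
    lesion = sr = None
    if kind == "two_tissue":
        sspec = SceneSpec(seed=stage_seed(seed, "scene"), **scene_cfg)
        cube, lesion, sr = make_two_tissue_cube(sspec)
        truth = cube.bands.copy()
    elif kind == "usaf":
        shape = tuple(scene_cfg.get("shape", (512, 512)))
        groups = tuple(scene_cfg.get("bar_groups", (16, 8, 4)))
        scene, regions = make_usaf_scene(groups=groups, shape=shape)
        scale = float(scene_cfg.get("intensity_scale", 2000.0))
        truth = (scene * scale)[None]
        cube = HSCube(bands=truth.copy(), wavelengths_nm=[510.0])
    elif kind == "flat":
        shape = tuple(scene_cfg.get("shape", (512, 512)))
        scale = float(scene_cfg.get("intensity_scale", 2000.0))
        truth = np.full((1,) + shape, scale)
        cube = HSCube(bands=truth.copy(), wavelengths_nm=[510.0])
    else:
        raise ValueError(f"unknown scene kind {kind!r}")
    rendered, _ = render_honeycomb(cube.bands, hc_spec)
    noisy = HSCube(bands=rendered, wavelengths_nm=cube.wavelengths_nm,
                   masks=dict(cube.masks))
    write_cube(noisy, os.path.join(out_dir, "simulated.tif"))
    log.info("simulate: %s scene, %d band(s), %dx%d",
             kind, noisy.n_bands, noisy.height, noisy.width)

    filt = HoneycombNotchFilter(**config.get("filter", {}))
    filtered_bands = filt.transform(noisy.bands)
    filtered = HSCube(bands=filtered_bands, wavelengths_nm=noisy.wavelengths_nm,
                      masks=dict(noisy.masks))
    write_cube(filtered, os.path.join(out_dir, "filtered.tif"))
    summary["defringe"] = {
        "peaks_per_band": [len(r) for r in filt.reports_],
        "window_sizes": sorted({int(p["n"]) for r in filt.reports_ for p in r}),
    }

    if regions is not None:
        gammas = config.get("metrics", {}).get("gamma", [0.5, 0.8])
        if np.isscalar(gammas):
            gammas = [gammas]
        summary["metrics"] = {}
        for g in gammas:
            rep = score_cube(filtered.bands, noisy.bands, regions, float(g))
            summary["metrics"][f"gamma={g}"] = {
                "mean_s": rep.mean_s, "mean_r": rep.mean_r,
                "mean_q": rep.mean_q, "sd_q": rep.sd_q,
            }

    if kind == "two_tissue":
        cls_cfg = dict(config.get("classify", {}))
        mode = cls_cfg.pop("mode", "gmm")
        drop = config.get("drop_bands", [0, 1])
        work = drop_bands(filtered, drop) if drop else filtered
        nri = build_nri_cube(work)
        table, retained = apply_exclusion_mask(nri, sr)
        if mode == "gmm":
            k = int(cls_cfg.pop("k", 10))
            model = gmm_fit(table, k=k, seed=stage_seed(seed, "classify"),
                            **cls_cfg)
            lm = gmm_predict(model, table)
            label_img = np.full(work.shape, -1, dtype=int)
            label_img.ravel()[retained] = lm.labels
            np.savetxt(os.path.join(out_dir, "labels.tsv"), label_img,
                       fmt="%d", delimiter="\t")
            overlap = {}
            for c in range(k):
                sel = label_img == c
                overlap[c] = float((sel & lesion).sum() / max(sel.sum(), 1))
            summary["classify"] = {"mode": "gmm", "k": k,
                                   "n_iterations": len(model.log_likelihood),
                                   "lesion_overlap_by_cluster": overlap}
        elif mode == "correlation":
            n_ref = int(cls_cfg.pop("n_reference_pixels", 100))
            ref = reference_spectrum(nri, lesion & ~sr, n_pixels=n_ref,
                                     seed=stage_seed(seed, "classify"))
            cm = correlation_map(nri, ref)
            np.savetxt(os.path.join(out_dir, "correlation.tsv"), cm.values,
                       fmt="%.6f", delimiter="\t")
            summary["classify"] = {
                "mode": "correlation",
                "mean_corr_lesion": float(np.nanmean(cm.values[lesion & ~sr])),
                "mean_corr_healthy": float(np.nanmean(cm.values[~lesion & ~sr])),
            }
        else:
            raise ValueError(f"unknown classify mode {mode!r}")
        write_mask(lesion, os.path.join(out_dir, "lesion_mask.png"))
        write_mask(sr, os.path.join(out_dir, "specular_mask.png"))

    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
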