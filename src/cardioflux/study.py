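"""Synthetic two-group study (CON vs MCT) and the end-to-end pipeline.

`gen_group_study` writes a directory of trace/oxygraph/image fixtures whose
per-cell ground-truth parameters are drawn around the group means of the
monocrotaline pulmonary-artery-hypertension model and its saline controls;
`run_study` pushes every fixture through the corresponding analyzer and
`summarize_study` reduces the result to group mean +/- SEM tables, so the
configured group-effect directions can be checked end to end.

Group means are study conditions, not tuning knobs.  Per-cell spreads are
reconstructed from the printed dispersion: SEM x sqrt(n) where the printed
value is a standard error, or the printed value directly where it can only
be a per-cell/per-section SD (see docs/methods.md); the manifest records
every drawn ground-truth value.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .caffeine import analyze_caffeine
from .clusters import cluster_density, segment_clusters
from .errors import ValidationError
from .io import compute_dff, compute_ratio, read_image, read_oxygraph, read_trace, write_image, write_oxygraph, write_trace
from .oxygraph import PsiCalibration, analyze_oxygraph
from .synth import (
    ClusterImageGenSpec,
    DEFAULT_FREE_CA_LADDER,
    OxygraphGenSpec,
    OxyStateSpec,
    TransientGenSpec,
    gen_caffeine_trace,
    gen_cluster_image,
    gen_oxygraph,
    gen_transient_trace,
)
from .transients import analyze_trace, steady_state_summary

#: group-level ground-truth parameters (mean, per-cell SD, n)
STUDY_GROUPS: dict = {
    "CON": {
        "cyto": dict(amplitude=1.26, amplitude_sd=0.31, tau=0.27, tau_sd=0.069,
                     ttp=0.08, ttp_sd=0.01, diastolic=1.0, n=12),
        "caffeine": dict(store=0.59, store_sd=0.137, tau=6.07, tau_sd=1.92, n=21),
        "mito": dict(amplitude=0.025, amplitude_sd=0.0063, ttp=0.165, ttp_sd=0.035,
                     tau=0.30, tau_sd=0.05, n=10),
        "tom20": dict(density=11.2, density_sd=4.2, area=0.034, area_sd=0.010, n=15),
        "ryr2": dict(density=5.0, density_sd=1.5, area=0.022, area_sd=0.005, n=15),
        "oxygraph": dict(leak_psi=-210.0, psi_sd=11.3, n=2),
    },
    "MCT": {
        "cyto": dict(amplitude=1.58, amplitude_sd=0.46, tau=0.27, tau_sd=0.069,
                     ttp=0.08, ttp_sd=0.01, diastolic=1.0, n=12),
        "caffeine": dict(store=0.78, store_sd=0.24, tau=4.75, tau_sd=0.80, n=16),
        "mito": dict(amplitude=0.033, amplitude_sd=0.0063, ttp=0.201, ttp_sd=0.047,
                     tau=0.30, tau_sd=0.05, n=10),
        "tom20": dict(density=14.9, density_sd=3.2, area=0.027, area_sd=0.010, n=15),
        "ryr2": dict(density=5.0, density_sd=1.5, area=0.016, area_sd=0.007, n=15),
        "oxygraph": dict(leak_psi=-200.0, psi_sd=11.3, n=2),
    },
}

#: effect directions configured into STUDY_GROUPS, as MCT-vs-CON comparisons
EXPECTED_DIRECTIONS: dict[str, str] = {
    "cyto_amplitude": ">",
    "caffeine_store": ">",
    "caffeine_tau": "<",
    "mito_amplitude": ">",
    "mito_ttp": ">",
    "tom20_density": ">",
    "tom20_area": "<",
    "ryr2_area": "<",
}

#: feasibility cap for drawn image parameters: density x mean area
_MAX_COVERAGE = 0.45


def _draw(rng, mean, sd, lo=1e-9, n_redraw=200):
    """Truncated normal draw: redraw while <= lo; returns (value, redraws)."""
    redraws = 0
    for _ in range(n_redraw):
        v = float(rng.normal(mean, sd))
        if v > lo:
            return v, redraws
        redraws += 1
    raise ValidationError(f"could not draw a positive value around {mean} +/- {sd}")


def gen_group_study(out_dir, seed: int, groups: dict | None = None) -> dict:
    """Write the full fixture set; returns (and writes) the manifest."""
    groups = groups or STUDY_GROUPS
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {
        "seed": seed,
        "groups": {g: {k: dict(v) for k, v in spec.items()} for g, spec in groups.items()},
        "expected_directions": dict(EXPECTED_DIRECTIONS),
        "truncated_redraws": 0,
        "cells": [],
    }

    def child_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    def note(**entry) -> None:
        manifest["cells"].append(entry)

    for group, spec in groups.items():
        gdir = out / group
        gdir.mkdir(exist_ok=True)

        g = spec["cyto"]
        for i in range(g["n"]):
            amp, r1 = _draw(rng, g["amplitude"], g["amplitude_sd"])
            tau, r2 = _draw(rng, g["tau"], g["tau_sd"])
            ttp, r3 = _draw(rng, g["ttp"], g["ttp_sd"])
            while ttp >= 0.9 * tau:
                ttp, r = _draw(rng, g["ttp"], g["ttp_sd"])
                r3 += r + 1
            manifest["truncated_redraws"] += r1 + r2 + r3
            t_spec = TransientGenSpec(
                seed=child_seed(), diastolic=g["diastolic"], amplitude=amp,
                time_to_peak_s=ttp, tau_decay_s=tau, stim_freq_hz=1.0, n_beats=15,
                noise_sd=0.02, mode="ratiometric",
                meta={"group": group, "cell_id": f"{group}_cyto_{i:02d}"},
            )
            trace, truth = gen_transient_trace(t_spec)
            path = write_trace(trace, gdir / f"cyto_{i:02d}.csv")
            note(group=group, modality="cyto", path=str(path.relative_to(out)), truth=truth)

        g = spec["caffeine"]
        for i in range(g["n"]):
            store, r1 = _draw(rng, g["store"], g["store_sd"])
            tau, r2 = _draw(rng, g["tau"], g["tau_sd"], lo=0.5)
            manifest["truncated_redraws"] += r1 + r2
            trace, truth = gen_caffeine_trace(
                store_amplitude=store, tau_efflux_s=tau, seed=child_seed(),
                pre_s=5.0, post_s=30.0, noise_sd=0.02,
                meta={"group": group, "cell_id": f"{group}_caff_{i:02d}"},
            )
            path = write_trace(trace, gdir / f"caffeine_{i:02d}.csv")
            note(group=group, modality="caffeine", path=str(path.relative_to(out)), truth=truth)

        g = spec["mito"]
        for i in range(g["n"]):
            amp, r1 = _draw(rng, g["amplitude"], g["amplitude_sd"])
            tau, r2 = _draw(rng, g["tau"], g["tau_sd"], lo=0.05)
            ttp, r3 = _draw(rng, g["ttp"], g["ttp_sd"])
            while ttp >= 0.9 * tau:
                ttp, r = _draw(rng, g["ttp"], g["ttp_sd"])
                r3 += r + 1
            manifest["truncated_redraws"] += r1 + r2 + r3
            t_spec = TransientGenSpec(
                seed=child_seed(), diastolic=0.0, amplitude=amp, time_to_peak_s=ttp,
                tau_decay_s=tau, stim_freq_hz=0.1, n_beats=8, noise_sd=0.10 * amp,
                mode="single", pre_quiet_s=2.0,
                meta={"group": group, "cell_id": f"{group}_mito_{i:02d}"},
            )
            trace, truth = gen_transient_trace(t_spec)
            path = write_trace(trace, gdir / f"mito_{i:02d}.csv")
            note(group=group, modality="mito", path=str(path.relative_to(out)), truth=truth)

        for channel in ("tom20", "ryr2"):
            g = spec[channel]
            for i in range(g["n"]):
                dens, area = 0.0, 0.0
                for _ in range(200):
                    dens, r1 = _draw(rng, g["density"], g["density_sd"], lo=1.0)
                    area, r2 = _draw(rng, g["area"], g["area_sd"], lo=0.004)
                    manifest["truncated_redraws"] += r1 + r2
                    if dens * area <= _MAX_COVERAGE:
                        break
                    manifest["truncated_redraws"] += 1
                i_spec = ClusterImageGenSpec(
                    seed=child_seed(), density_per_um2=dens, mean_area_um2=area,
                    channel_label=channel.upper(),
                    meta={"group": group, "image_id": f"{group}_{channel}_{i:02d}"},
                )
                img, truth = gen_cluster_image(i_spec)
                path = write_image(img, gdir / f"{channel}_{i:02d}.tif")
                truth = {k: v for k, v in truth.items() if k not in ("x_um", "y_um", "area_um2")}
                truth["target_density"] = dens
                truth["target_mean_area"] = area
                note(group=group, modality=channel, path=str(path.relative_to(out)), truth=truth)

        g = spec["oxygraph"]
        for i in range(g["n"]):
            psi, r1 = _draw(rng, -g["leak_psi"], g["psi_sd"], lo=100.0)
            manifest["truncated_redraws"] += r1
            calib = PsiCalibration.from_tissue_mass(2.0)
            states = (
                OxyStateSpec("GMP", 300.0, -0.010, -psi),
                OxyStateSpec("ADP_HEX", 300.0, -0.050, -psi + 50.0),
                OxyStateSpec("CACL2", 300.0, -0.055, -psi + 60.0, dose="0.3"),
                OxyStateSpec("FCCP", 200.0, -0.060, 0.0),
            )
            o_spec = OxygraphGenSpec(
                seed=child_seed(), states=states, calib=calib,
                noise_sd_o2=0.2, noise_sd_saf=0.002,
                free_ca_ladder=DEFAULT_FREE_CA_LADDER,
                meta={"group": group, "chamber_id": f"{group}_oxy_{i:02d}"},
            )
            rec, truth = gen_oxygraph(o_spec)
            path = write_oxygraph(rec, gdir / f"oxy_{i:02d}.csv")
            note(group=group, modality="oxygraph", path=str(path.relative_to(out)), truth=truth)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# analysis side


def _robust_summary(params, n_last: int):
    """Steady-state summary tolerating cells with fewer accepted beats."""
    accepted = sum(1 for p in params if p.accepted and p.tau_valid)
    return steady_state_summary(params, n_last=min(n_last, max(accepted, 1)))


def _analyze_entry(entry: dict, root: Path) -> dict:
    path = root / entry["path"]
    group, modality = entry["group"], entry["modality"]
    row: dict = {"group": group, "modality": modality, "path": entry["path"]}
    if modality == "cyto":
        ratio = compute_ratio(read_trace(path))
        summary = _robust_summary(analyze_trace(ratio), n_last=10)
        row.update(
            amplitude=summary.mean["amplitude"], tau=summary.mean["tau_decay"],
            ttp=summary.mean["time_to_peak"], rate=summary.mean["max_rate_of_rise"],
        )
    elif modality == "mito":
        trace = read_trace(path)
        dff = compute_dff(trace, tuple(entry["truth"]["f0_window"]))
        summary = _robust_summary(analyze_trace(dff), n_last=5)
        row.update(
            amplitude=summary.mean["amplitude"], tau=summary.mean["tau_decay"],
            ttp=summary.mean["time_to_peak"],
        )
    elif modality == "caffeine":
        res = analyze_caffeine(compute_ratio(read_trace(path)))
        row.update(store=res.store_amplitude, tau=res.tau_efflux)
    elif modality in ("tom20", "ryr2"):
        cs = segment_clusters(read_image(path))
        interior = cs.interior()
        row.update(
            density=cluster_density(cs).mean_per_tile,
            area=float(np.mean(interior.areas_um2)) if len(interior) else math.nan,
            n_clusters=len(cs),
        )
    elif modality == "oxygraph":
        rec = read_oxygraph(path)
        calib = PsiCalibration.from_tissue_mass(rec.tissue_mass_mg)
        states = analyze_oxygraph(rec, calib)
        for st in states:
            if st.label == "CI_Leak":
                row.update(leak_psi=st.psi, leak_flux=st.flux)
            elif st.label == "CI_OXPHOS":
                row.update(oxphos_flux=st.flux, oxphos_psi=st.psi)
    return row


def run_study(study_dir) -> pd.DataFrame:
    """Analyze every fixture listed in a study manifest."""
    root = Path(study_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    return pd.DataFrame([_analyze_entry(e, root) for e in manifest["cells"]])


def summarize_study(df: pd.DataFrame) -> pd.DataFrame:
    """Group x modality mean +/- SEM of every recovered metric."""
    metrics = [c for c in df.columns if c not in ("group", "modality", "path")]
    rows = []
    for (group, modality), sub in df.groupby(["group", "modality"]):
        for m in metrics:
            vals = sub[m].dropna()
            if not len(vals):
                continue
            rows.append(
                {
                    "group": group, "modality": modality, "metric": m,
                    "mean": float(vals.mean()),
                    "sem": float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0,
                    "n": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)


def effect_directions(summary: pd.DataFrame) -> dict[str, bool]:
    """Check each configured MCT-vs-CON direction on the recovered means."""
    out = {}
    for key, op in EXPECTED_DIRECTIONS.items():
        modality, metric = key.split("_", 1)
        sel = summary[(summary.modality == modality) & (summary.metric == metric)]
        con = float(sel[sel.group == "CON"]["mean"].iloc[0])
        mct = float(sel[sel.group == "MCT"]["mean"].iloc[0])
        out[key] = (mct > con) if op == ">" else (mct < con)
    return out
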