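"""End-to-end orchestration: simulate → reconstruct → features → classify.

Two entry points matter in practice:

* :func:`extract_features_for_cells` / :func:`simulate_feature_table` —
  the in-memory path used by analyses and by the test suite,
* :func:`run_all` — the file-producing experiment driver configured by a
  :class:`PipelineConfig` (YAML-loadable), writing holograms, phase/OT
  maps, the feature CSV, the classification report and a summary of
  per-stress-level box-plot statistics (median, quartiles, 1.5·IQR
  whiskers, outlier count).

Stress sweeps use a paired design: each cell index reuses the same
geometry-jitter and roughness seeds at every stress level, and only the
illumination noise is re-drawn, so level-to-level median trends measure
the deformation rather than the geometry jitter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from .morphometry import extract_morph_features, segment_head, HeadMask
from .phantom import PhantomConfig, SpermPhantom, make_phantom, stress_transform
from .reconstruct import PhaseMap, phase_to_ot, reconstruct_phase
from .simulate import (
    CarrierSpec,
    ClassDef,
    Hologram,
    IlluminationModel,
    JitterSpec,
    PSEUDO_THERMAL_PRESET,
    generate_dataset,
    make_cell,
    synthesize_hologram,
)
from .texture import TextureConfig, extract_texture_features

__all__ = [
    "PipelineConfig",
    "cell_features",
    "extract_features_for_cells",
    "simulate_feature_table",
    "sweep_stress_levels",
    "box_stats",
    "run_all",
    "make_fixtures",
]

log = logging.getLogger("holosperm")

ALL_FEATURES = ["max_phase"] + _classify.FEATURE_COLUMNS


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one experiment needs, serializable to/from YAML."""

    base_seed: int = 1
    n_per_class: int = 20
    stress_control: float = 0.0
    stress_test: float = 1.0
    illumination: str = "pseudo_thermal"
    train_fraction: float = 0.6
    kernel: str = "linear"
    C: float = 1.0
    window: str = "gaussian"
    radius_frac: float = 1.0 / 3.0
    poly_order: int = 2
    geometry: str = "reflection"
    mask_mode: str = "auto"  # auto | ground_truth
    out_dir: str = "holosperm_run"
    write_holograms: bool = True
    write_maps: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def illumination_model(self) -> IlluminationModel:
        from . import simulate

        return (
            simulate.COHERENT_PRESET
            if self.illumination == "coherent"
            else simulate.PSEUDO_THERMAL_PRESET
        )


def cell_features(
    phantom: SpermPhantom,
    hologram: Hologram | None,
    use_ground_truth_mask: bool = False,
    radius_frac: float = 1.0 / 3.0,
    window: str = "gaussian",
    texture_config: TextureConfig | None = None,
) -> dict:
    """Reconstruct (or use ground truth) and extract the full feature row.

    With ``hologram=None`` the phantom's ground-truth phase field is used
    directly, which isolates the feature definitions from reconstruction
    error in oracle tests.
    """
    if hologram is None:
        from .reconstruct import OpticsMeta

        pm = PhaseMap(
            values=phantom.phase, wrapped=False, background_corrected=True,
            meta=OpticsMeta(dx_um=phantom.config.dx_um, dy_um=phantom.config.dy_um),
        )
    else:
        pm = reconstruct_phase(hologram, window=window, radius_frac=radius_frac)
    mask = (
        HeadMask(phantom.head_mask.copy(), provenance="ground_truth")
        if use_ground_truth_mask
        else segment_head(pm)
    )
    ot = phase_to_ot(pm)
    mf = extract_morph_features(pm, ot, mask)
    tf = extract_texture_features(pm, mask, texture_config)
    return {
        "max_phase": mf.max_phase, "ot_max": mf.ot_max,
        "S": mf.S, "V": mf.V, "S_over_V": mf.S_over_V,
        "sphericity": mf.sphericity,
        "mean": tf.mean, "variance": tf.variance, "kurtosis": tf.kurtosis,
        "skewness": tf.skewness, "entropy": tf.entropy, "energy": tf.energy,
    }


def extract_features_for_cells(
    cells, manifest: pd.DataFrame, use_ground_truth_mask: bool = False, **kw
) -> pd.DataFrame:
    rows = []
    for (ph, holo), (_, mrow) in zip(cells, manifest.iterrows()):
        t0 = time.perf_counter()
        feats = cell_features(ph, holo, use_ground_truth_mask, **kw)
        feats.update(cell_id=mrow["cell_id"], label=int(mrow["label"]),
                     stress=float(mrow["stress"]))
        rows.append(feats)
        log.debug("features %s in %.2fs", mrow["cell_id"], time.perf_counter() - t0)
    return pd.DataFrame(rows)


def simulate_feature_table(
    n_per_class: int,
    base_seed: int,
    stress_levels: tuple[float, float] = (0.0, 1.0),
    illum: IlluminationModel = PSEUDO_THERMAL_PRESET,
    use_ground_truth_mask: bool = False,
) -> pd.DataFrame:
    """Two-class dataset straight to a feature table (no files)."""
    cells, manifest = generate_dataset(
        n_per_class,
        [ClassDef(0, stress_levels[0], illum), ClassDef(1, stress_levels[1], illum)],
        base_seed,
    )
    return extract_features_for_cells(cells, manifest, use_ground_truth_mask)


def sweep_stress_levels(
    levels,
    n_per_level: int,
    base_seed: int,
    illum: IlluminationModel = PSEUDO_THERMAL_PRESET,
    use_ground_truth_mask: bool = False,
    reconstruct: bool = True,
    base_config: PhantomConfig | None = None,
    jitter: JitterSpec | None = None,
) -> pd.DataFrame:
    """Paired stress sweep: per-cell geometry shared across all levels."""
    base_config = base_config or PhantomConfig()
    jitter = jitter or JitterSpec()
    carrier = CarrierSpec()
    rows = []
    for i in range(n_per_level):
        cell_ss = np.random.SeedSequence([base_seed, i])
        for li, s in enumerate(levels):
            ph, illum_seed = make_cell(base_config, float(s), jitter, cell_ss)
            holo = (
                synthesize_hologram(ph, carrier, illum, seed=illum_seed + li)
                if reconstruct else None
            )
            feats = cell_features(ph, holo, use_ground_truth_mask)
            feats.update(cell_id=f"s{li}_{i:04d}", stress=float(s),
                         label=int(s > 0))
            rows.append(feats)
    return pd.DataFrame(rows)


def box_stats(values: np.ndarray) -> dict:
    """Whisker-box statistics: median, quartiles, 1.5·IQR whiskers, outliers."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "whisker_low": float(inside.min()), "whisker_high": float(inside.max()),
        "n_outliers": int(((v < lo_fence) | (v > hi_fence)).sum()),
        "n": int(v.size),
    }


def run_all(config: PipelineConfig) -> Path:
    """Run one full experiment into ``config.out_dir``; returns the path.

    Produces holograms (optionally), per-cell phase/OT maps (optionally),
    ``features.csv``, ``report.json`` + ``roc.csv``, ``summary.json``
    (per-class box statistics for every feature) and ``run_manifest.json``
    with the config, its hash and the package version.
    """
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    illum = config.illumination_model()
    t0 = time.perf_counter()
    cells, manifest = generate_dataset(
        config.n_per_class,
        [ClassDef(0, config.stress_control, illum),
         ClassDef(1, config.stress_test, illum)],
        config.base_seed,
        out_dir=out / "holograms" if config.write_holograms else None,
        overwrite=True,
    )
    log.info("simulated %d holograms in %.1fs", len(cells), time.perf_counter() - t0)

    features = extract_features_for_cells(
        cells, manifest,
        use_ground_truth_mask=(config.mask_mode == "ground_truth"),
        radius_frac=config.radius_frac, window=config.window,
    )
    features.to_csv(out / "features.csv", index=False, float_format="%.10g")

    if config.write_maps:
        from .io import save_phase_map, save_ot_map

        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        for (ph, holo), cid in zip(cells, manifest["cell_id"]):
            pm = reconstruct_phase(holo, window=config.window,
                                   radius_frac=config.radius_frac)
            save_phase_map(pm, maps_dir / f"{cid}_phase.tiff")
            save_ot_map(phase_to_ot(pm), maps_dir / f"{cid}_ot.tiff")

    report = _classify.run_classification(
        features, train_fraction=config.train_fraction,
        kernel=config.kernel, C=config.C, seed=config.base_seed,
        out_report=out / "report.json", out_roc=out / "roc.csv",
    )

    summary = {
        "per_class": {
            str(lbl): {
                feat: box_stats(grp[feat].to_numpy())
                for feat in ALL_FEATURES
            }
            for lbl, grp in features.groupby("label")
        }
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "run_manifest.json").write_text(json.dumps({
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "version": __version__,
        "n_cells": len(cells),
        "auc": report.auc,
        "accuracy": report.accuracy,
    }, indent=2, sort_keys=True))
    return out


# ---------------------------------------------------------------------------
# test/doc fixture generation


def make_fixtures(seed: int, out_dir: str | Path) -> dict:
    """Write the small deterministic fixture set used by tests and docs.

    Contents: a hemisphere height field with its closed-form S and V, a
    wrapped 6π phase ramp, a two-level checkerboard, and 3 phantoms per
    class (control / stressed).  Returns {relative path: sha256} checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checks: dict[str, str] = {}

    r_px, dx = 60, 0.1
    n = 2 * r_px + 11
    c = n // 2
    yy, xx = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
    r_um = r_px * dx
    hemi = np.sqrt(np.clip(r_um**2 - ((xx * dx) ** 2 + (yy * dx) ** 2), 0, None))
    np.save(out / "hemisphere_um.npy", hemi)
    (out / "hemisphere_truth.json").write_text(json.dumps({
        "radius_um": r_um, "dx_um": dx,
        "V_um3": (2.0 / 3.0) * np.pi * r_um**3,
        "S_um2": 3.0 * np.pi * r_um**2,
    }, indent=2, sort_keys=True))

    ramp = np.tile(np.linspace(0, 6 * np.pi, 256), (64, 1))
    wrapped = np.angle(np.exp(1j * ramp))
    np.save(out / "ramp_wrapped.npy", wrapped)

    checker = np.indices((32, 32)).sum(axis=0) % 2
    np.save(out / "checkerboard.npy", checker)

    for k, s in enumerate([0.0, 0.0, 0.0, 1.0, 1.0, 1.0]):
        ss = np.random.SeedSequence([seed, k])
        ph, _ = make_cell(PhantomConfig(), s, JitterSpec(), ss)
        np.save(out / f"phantom_{k}_s{int(s)}.npy", ph.phase.astype(np.float32))

    for p in sorted(out.iterdir()):
        if p.suffix in (".npy", ".json"):
            checks[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "checksums.json").write_text(json.dumps(checks, indent=2, sort_keys=True))
    return checks
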