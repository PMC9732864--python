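"""Pipeline orchestration: simulate -> localize -> distances -> rates -> fit.

Each stage is a plain function over files in a working directory, so the
CLI subcommands map one-to-one onto them and any stage can be rerun in
isolation.  The report bundle mirrors the analysis tables: per-pathology
regressions for each distance family, the distance-family comparison,
moderation results, the D_max table with a Welch ANOVA, logistic
fast-ripple occurrence models, and a visual slope table.  A run manifest
records the seed, configuration hash and library versions; every excluded
channel is logged with a reason.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as edio
from .cohort import Cohort, CohortSpec, make_cohort
from .events import (
    EVENT_TYPES,
    RATE_COLUMNS,
    compute_rates,
    dmax,
    montage_midpoints,
    summarize_rates,
)
from .geometry import (
    euclidean_com_distance,
    euclidean_edge_distance,
    extrapolate_grid,
    geodesic_distances,
)
from .stats import (
    logistic_occurrence,
    moderation,
    moderation_joint,
    ols_hc3,
    visual_slope_table,
    welch_anova,
)

logger = logging.getLogger("ecogdist")

FAMILY_COLUMNS = {"edge": "d_edge_mm", "com": "d_com_mm", "geo": "d_geo_mm"}


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    ``input_dir`` must hold a cohort in the on-disk layout the generator
    writes (or ``simulate`` holds generator settings and the cohort is
    produced under ``out_dir/cohort`` first).
    """

    out_dir: str | Path = "ecogdist_out"
    input_dir: str | Path | None = None
    simulate: dict | None = None
    distance_families: tuple[str, ...] = ("edge", "com", "geo")
    montage_direction: str = "row"
    n_boot: int = 1000
    seed: int = 0
    alpha: float = 0.05
    chord_tol: float = 1.0
    snap_tol: float = 1.5
    n_ring: int = 3

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("bootstrap count must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        bad = set(self.distance_families) - set(FAMILY_COLUMNS)
        if bad:
            raise ValueError(f"unknown distance families {sorted(bad)}")
        if self.input_dir is None and self.simulate is None:
            raise ValueError("either input_dir or simulate settings required")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        known = set(cls.__dataclass_fields__)
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config fields {sorted(bad)}")
        if "distance_families" in raw:
            raw["distance_families"] = tuple(raw["distance_families"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {
            "out_dir": str(self.out_dir),
            "input_dir": None if self.input_dir is None else str(self.input_dir),
            "simulate": self.simulate,
            "distance_families": list(self.distance_families),
            "montage_direction": self.montage_direction,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "alpha": self.alpha,
            "chord_tol": self.chord_tol,
            "snap_tol": self.snap_tol,
            "n_ring": self.n_ring,
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig) -> Path:
    """Generate a synthetic cohort under out_dir/cohort."""
    settings = dict(config.simulate or {})
    settings.setdefault("seed", config.seed)
    spec = CohortSpec.from_dict(settings)
    cohort_dir = Path(config.out_dir) / "cohort"
    make_cohort(spec, out_dir=cohort_dir)
    logger.info("simulated cohort written to %s", cohort_dir)
    return cohort_dir


def _patient_dirs(input_dir: Path) -> list[Path]:
    dirs = sorted(
        d for d in input_dir.iterdir() if d.is_dir() and (d / "electrodes.tsv").exists()
    )
    if not dirs:
        raise FileNotFoundError(f"no patient directories under {input_dir}")
    return dirs


def stage_localize(config: PipelineConfig, input_dir: Path) -> None:
    """Extrapolate hidden electrodes for every array of every patient."""
    for pdir in _patient_dirs(input_dir):
        surface = edio.load_surface(pdir / "surface.ply")
        table = edio.load_electrodes(pdir / "electrodes.tsv")
        arrays = edio.electrode_table_to_arrays(table)
        filled = {}
        for key, arr in arrays.items():
            filled[key] = extrapolate_grid(
                arr, surface, chord_tol=config.chord_tol, snap_tol=config.snap_tol
            )
        out = edio.arrays_to_electrode_table(filled)
        edio.save_electrodes(out, pdir / "electrodes_localized.tsv")
        logger.info("localized %d arrays for %s", len(filled), pdir.name)


def stage_distances(config: PipelineConfig, input_dir: Path) -> pd.DataFrame:
    """Bipolar montage, midpoints and the selected distance families."""
    rows = []
    for pdir in _patient_dirs(input_dir):
        surface = edio.load_surface(pdir / "surface.ply")
        lesion = edio.load_lesion(pdir / "lesion.nii")
        table = edio.load_electrodes(pdir / "electrodes_localized.tsv")
        arrays = edio.electrode_table_to_arrays(table)
        for (pid, rid, aid), arr in arrays.items():
            mids = montage_midpoints(arr, direction=config.montage_direction)
            mids.insert(0, "patient_id", pid)
            mids.insert(1, "recording_id", rid)
            pts = mids[["mid_x", "mid_y", "mid_z"]].to_numpy(float)
            if "edge" in config.distance_families:
                mids["d_edge_mm"] = [euclidean_edge_distance(p, lesion) for p in pts]
            if "com" in config.distance_families:
                mids["d_com_mm"] = [euclidean_com_distance(p, lesion) for p in pts]
            if "geo" in config.distance_families:
                mids["d_geo_mm"] = geodesic_distances(
                    pts,
                    lesion,
                    surface,
                    n_ring=config.n_ring,
                    labels=mids["channel_id"].tolist(),
                )
            rows.append(mids)
    channels = pd.concat(rows, ignore_index=True)
    keep = ["patient_id", "recording_id", "channel_id", "mid_x", "mid_y", "mid_z"]
    keep += [FAMILY_COLUMNS[f] for f in config.distance_families]
    return channels[keep]


def stage_rates(
    config: PipelineConfig, input_dir: Path, channels: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach per-channel biomarker rates; drop and log excluded channels."""
    events = edio.load_events(input_dir / "events.csv")
    art_path = input_dir / "artifacts.csv"
    artifacts = edio.load_artifacts(art_path) if art_path.exists() else None
    rates = compute_rates(events, channels, artifacts=artifacts)
    merged = channels.merge(
        rates, on=["patient_id", "recording_id", "channel_id"], how="inner"
    )
    exclusions = []
    if artifacts is not None:
        dropped = channels.merge(
            artifacts, on=["patient_id", "recording_id", "channel_id"], how="inner"
        )
        for _, row in dropped.iterrows():
            exclusions.append(
                {
                    "patient_id": row["patient_id"],
                    "recording_id": row["recording_id"],
                    "channel_id": row["channel_id"],
                    "reason": "artifact",
                }
            )
            logger.info(
                "excluded channel %s/%s/%s: artifact",
                row["patient_id"],
                row["recording_id"],
                row["channel_id"],
            )
    patients = pd.read_csv(input_dir / "patients.csv")
    merged = merged.merge(patients, on="patient_id", how="left")
    return merged, pd.DataFrame(
        exclusions, columns=["patient_id", "recording_id", "channel_id", "reason"]
    )


def stage_fit(config: PipelineConfig, channels: pd.DataFrame) -> pd.DataFrame:
    """Per (pathology x event type x distance family) robust regression.

    Every combination gets a row; combinations without events (or with a
    constant rate) carry NaN statistics and a note, mirroring the em-dash
    cells of the descriptive tables.
    """
    rows = []
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF17]))
    groups = [("all", channels)] + [
        (p, g) for p, g in channels.groupby("pathology", sort=True)
    ]
    for label, g in groups:
        for etype in EVENT_TYPES:
            x = g[RATE_COLUMNS[etype]].to_numpy(float)
            for fam in config.distance_families:
                y = g[FAMILY_COLUMNS[fam]].to_numpy(float)
                base = {
                    "pathology": label,
                    "event_type": etype,
                    "distance_family": fam,
                    "n": len(g),
                }
                if x.sum() == 0:
                    rows.append({**base, "note": "no events"})
                    continue
                if np.ptp(x) == 0:
                    rows.append({**base, "note": "constant rate"})
                    continue
                res = ols_hc3(y, x, n_boot=config.n_boot, seed=rng)
                rows.append(
                    {
                        **base,
                        "slope": res.slope,
                        "intercept": res.intercept,
                        "hc3_se": res.hc3_se,
                        "t_value": res.t_value,
                        "df_den": res.df_den,
                        "p_value": res.p_value,
                        "eta_squared": res.eta_squared,
                        "effect_class": res.effect_class,
                        "ci_low": res.bootstrap_ci_low,
                        "ci_high": res.bootstrap_ci_high,
                        "significant": res.p_value <= config.alpha,
                        "note": "",
                    }
                )
    return pd.DataFrame(rows)


def family_comparison(config: PipelineConfig, regressions: pd.DataFrame) -> pd.DataFrame:
    """Which distance family correlates most strongly, per pathology/type."""
    rows = []
    fitted = regressions.dropna(subset=["eta_squared"]) if "eta_squared" in regressions else regressions.iloc[0:0]
    for (pat, etype), g in fitted.groupby(["pathology", "event_type"], sort=True):
        best = g.sort_values(
            ["eta_squared", "distance_family"], ascending=[False, True]
        ).iloc[0]
        rows.append(
            {
                "pathology": pat,
                "event_type": etype,
                "best_family": best["distance_family"],
                "best_eta_squared": best["eta_squared"],
                "best_p_value": best["p_value"],
            }
        )
    return pd.DataFrame(rows)


def stage_moderate(config: PipelineConfig, channels: pd.DataFrame) -> dict:
    """Pathology (categorical) and lesion-volume (continuous) moderation.

    Runs on the lesion-edge distance with both moderators in one joint
    model, so the volume test is adjusted for pathology (and vice versa).
    Pathology levels whose rates are constant for a biomarker — e.g.
    fast ripples never recorded — are dropped from that biomarker's model
    with a note; if fewer than two levels remain the test is skipped.
    """
    out: dict = {}
    for etype in EVENT_TYPES:
        x = channels[RATE_COLUMNS[etype]].to_numpy(float)
        y = channels["d_edge_mm"].to_numpy(float)
        m = channels["pathology"].to_numpy()
        vol = channels["lesion_volume_cm3"].to_numpy(float)
        keep_levels = [
            lv
            for lv in pd.unique(m)
            if np.ptp(x[m == lv]) > 0 and (m == lv).sum() >= 3
        ]
        dropped = sorted(set(m) - set(keep_levels))
        entry: dict = {"dropped_levels": dropped}
        sel = np.isin(m, keep_levels)
        if len(keep_levels) >= 2 and np.ptp(vol[sel]) > 0:
            entry["n"] = int(sel.sum())
            try:
                joint = moderation_joint(y[sel], x[sel], m[sel], vol[sel])
                entry["pathology"] = joint["pathology"].to_dict()
                entry["lesion_volume"] = joint["lesion_volume"].to_dict()
            except ValueError as exc:
                # volume collinear with pathology (e.g. one patient per
                # level): fall back to the categorical moderator alone
                res = moderation(y[sel], x[sel], m[sel], kind="categorical")
                entry["pathology"] = res.to_dict()
                entry["lesion_volume"] = None
                entry["note"] = f"volume moderator dropped: {exc}"
        else:
            entry["pathology"] = None
            entry["lesion_volume"] = None
            entry["note"] = "fewer than two usable pathology levels"
        out[etype] = entry
    return out


def stage_dmax(config: PipelineConfig, channels: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """D_max table and the Welch ANOVA across biomarker types."""
    table = dmax(channels, distance_col="d_edge_mm")
    groups = [
        table.loc[table["event_type"] == t, "distance_mm"].to_numpy(float)
        for t in EVENT_TYPES
    ]
    usable = [g for g in groups if len(g) >= 2 and np.ptp(g) > 0]
    if len(usable) >= 2:
        res = welch_anova(usable)
        welch = {
            "f_value": res.f_value,
            "df_num": res.df_num,
            "df_den": res.df_den,
            "p_value": res.p_value,
            "n_groups": len(usable),
        }
    else:
        welch = {"note": "fewer than two usable D_max groups"}
    return table, welch


def stage_logistic(config: PipelineConfig, channels: pd.DataFrame) -> dict:
    """Fast-ripple occurrence vs lesion-edge distance, overall and by pathology."""
    out: dict = {}
    occ = (channels[RATE_COLUMNS["fast_ripple"]] > 0).astype(int).to_numpy()
    d = channels["d_edge_mm"].to_numpy(float)
    try:
        out["all"] = logistic_occurrence(occ, d).to_dict()
    except ValueError as exc:
        out["all"] = {"note": str(exc)}
    for pat, g in channels.groupby("pathology", sort=True):
        occ = (g[RATE_COLUMNS["fast_ripple"]] > 0).astype(int).to_numpy()
        d = g["d_edge_mm"].to_numpy(float)
        try:
            out[pat] = logistic_occurrence(occ, d).to_dict()
        except ValueError as exc:
            out[pat] = {"note": str(exc)}
    return out


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------


def run(config: PipelineConfig) -> Path:
    """Run every stage and write the report bundle; returns the out dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.input_dir is not None:
        input_dir = Path(config.input_dir)
        if not input_dir.exists():
            raise FileNotFoundError(f"input directory {input_dir} does not exist")
    else:
        input_dir = stage_simulate(config)

    stage_localize(config, input_dir)
    channels = stage_distances(config, input_dir)
    channels, exclusions = stage_rates(config, input_dir, channels)
    edio.save_channel_table(channels, out / "channels.csv")
    exclusions.to_csv(out / "exclusions.csv", index=False)

    summary = summarize_rates(channels.assign(epoch_minutes=1.0))
    summary.to_csv(out / "rate_summary.csv", index=False, float_format=edio.FLOAT_FMT)

    regressions = stage_fit(config, channels)
    regressions.to_csv(out / "regressions.csv", index=False, float_format=edio.FLOAT_FMT)
    family_comparison(config, regressions).to_csv(
        out / "family_comparison.csv", index=False, float_format=edio.FLOAT_FMT
    )

    if "edge" in config.distance_families:
        _json_dump(stage_moderate(config, channels), out / "moderation.json")
        table, welch = stage_dmax(config, channels)
        table.to_csv(out / "dmax.csv", index=False, float_format=edio.FLOAT_FMT)
        _json_dump(welch, out / "welch.json")
        _json_dump(stage_logistic(config, channels), out / "logistic.json")
        patients = pd.read_csv(input_dir / "patients.csv")
        pathology_of = dict(zip(patients["patient_id"], patients["pathology"]))
        visual_slope_table(table, pathology_of).to_csv(
            out / "visual_slopes.csv", index=False, float_format=edio.FLOAT_FMT
        )

    import scipy
    import statsmodels

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_channels": int(len(channels)),
        "n_excluded": int(len(exclusions)),
        "versions": {
            "ecogdist": __import__("ecogdist").__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    _json_dump(manifest, out / "manifest.json")
    logger.info("report bundle written to %s", out)
    return out
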