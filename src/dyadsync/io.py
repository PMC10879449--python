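"""Run configuration and plain-text readers/writers for all pipeline schemas.

Interchange formats are deliberately simple text: beat CSVs (one ``t_sec``
column per participant per task), RSA CSVs, posterior CSVs, screening CSVs,
agreement JSON, and a cohort manifest JSON.  Every file written carries the
run's config hash and seed in a leading comment line (CSV) or top-level keys
(JSON) so outputs are traceable to the configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dsem import MCMCConfig, PARAM_NAMES, SynchronyCall, VARPosterior
from .errors import ConfigError
from .ibi import (
    BeatSeries,
    DEFAULT_JUMP_FRACTION,
    DEFAULT_PHYSIO_BOUNDS_MS,
    IBISeries,
)
from .spectral import ADULT_BAND, DEFAULT_CHILD_BANDS, RSASeries, BandSpec, SpectralConfig
from .stationarity import DyadScreen
from .synthetic import ArtifactSpec, CohortSpec

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "write_beats_csv",
    "read_beats_csv",
    "write_ibi_csv",
    "read_ibi_csv",
    "write_rsa_csv",
    "read_rsa_csv",
    "write_manifest",
    "read_manifest",
    "write_posteriors_csv",
    "write_screening_csv",
    "write_calls_csv",
    "read_calls_csv",
    "write_agreement_json",
]


@dataclass(frozen=True)
class RunConfig:
    """Validated end-to-end run settings; defaults mirror the study design."""

    seed: int = 0
    out_dir: str = "dyadsync_out"
    # cohort
    n_dyads: int = 28
    duration_s: float = 300.0
    task_labels: tuple[str, ...] = ("conflict", "planning")
    effect_size: float = 0.3
    regime_mix: dict = field(
        default_factory=lambda: {
            "parent_driven": {"positive": 0.25, "negative": 0.25, "null": 0.5},
            "child_driven": {"positive": 0.25, "negative": 0.25, "null": 0.5},
        }
    )
    unusable: tuple[tuple[str, str], ...] = ()
    ectopic_rate: float = 0.5
    dropout_segments: tuple[tuple[float, float], ...] = ()
    # cleaning
    physio_bounds_ms: tuple[float, float] = DEFAULT_PHYSIO_BOUNDS_MS
    jump_fraction: float = DEFAULT_JUMP_FRACTION
    # spectral
    adult_band: tuple[float, float] = ADULT_BAND
    child_bands: dict = field(
        default_factory=lambda: {f"{lo}-{hi}": list(b) for (lo, hi), b in DEFAULT_CHILD_BANDS.items()}
    )
    taper_family: str = "dpss"
    n_tapers: int = 3
    power_floor: float = 1e-6
    # screening / modelling
    alpha: float = 0.05
    mcmc_max_iterations: int = 10_000
    mcmc_min_iterations: int = 1_000
    mcmc_check_interval: int = 500
    mcmc_n_chains: int = 2
    psr_threshold: float = 1.05

    def __post_init__(self) -> None:
        checks = [
            (self.n_dyads >= 1, "n_dyads"),
            (self.duration_s >= 64, "duration_s"),
            (len(self.task_labels) >= 1, "task_labels"),
            (0 < self.alpha < 1, "alpha"),
            (self.mcmc_n_chains >= 2, "mcmc_n_chains"),
            (self.psr_threshold > 1, "psr_threshold"),
            (self.power_floor > 0, "power_floor"),
            (self.physio_bounds_ms[0] < self.physio_bounds_ms[1], "physio_bounds_ms"),
            (0 < self.adult_band[0] < self.adult_band[1] < 2, "adult_band"),
        ]
        for ok, key in checks:
            if not ok:
                raise ConfigError(f"invalid config value for key {key!r}")

    def spectral_config(self) -> SpectralConfig:
        child_bands = {}
        for key, edges in self.child_bands.items():
            lo, hi = (int(p) for p in str(key).split("-"))
            child_bands[(lo, hi)] = (float(edges[0]), float(edges[1]))
        return SpectralConfig(
            adult_band=tuple(self.adult_band),
            child_bands=child_bands,
            taper_family=self.taper_family,
            n_tapers=self.n_tapers,
            power_floor=self.power_floor,
        )

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_dyads=self.n_dyads,
            regime_mix=self.regime_mix,
            task_labels=tuple(self.task_labels),
            duration_s=self.duration_s,
            seed=self.seed,
            effect_size=self.effect_size,
            artifacts=ArtifactSpec(
                ectopic_rate=self.ectopic_rate,
                dropout_segments=tuple(tuple(s) for s in self.dropout_segments),
            ),
            unusable=tuple(tuple(u) for u in self.unusable),
        )

    def mcmc_config(self, seed: int) -> MCMCConfig:
        return MCMCConfig(
            n_chains=self.mcmc_n_chains,
            max_iterations=self.mcmc_max_iterations,
            min_iterations=self.mcmc_min_iterations,
            check_interval=self.mcmc_check_interval,
            psr_threshold=self.psr_threshold,
            seed=seed,
        )


def config_hash(config: RunConfig) -> str:
    """Hash of the scientific settings; the output location does not matter."""
    fields = {k: v for k, v in asdict(config).items() if k != "out_dir"}
    payload = json.dumps(fields, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config file, apply overrides, and validate every key."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("task_labels", "physio_bounds_ms", "adult_band"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    if "unusable" in data:
        data["unusable"] = tuple(tuple(u) for u in data["unusable"])
    if "dropout_segments" in data:
        data["dropout_segments"] = tuple(tuple(s) for s in data["dropout_segments"])
    try:
        return RunConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def _header(tag: str) -> str:
    return f"# {tag}\n"


def _write_df(df: pd.DataFrame, path: Path, tag: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(tag))
        df.to_csv(fh, index=False, lineterminator="\n")


def write_beats_csv(beats: BeatSeries, path: str | Path, tag: str = "dyadsync") -> None:
    _write_df(pd.DataFrame({"t_sec": beats.times}), Path(path), tag)


def read_beats_csv(path: str | Path) -> BeatSeries:
    df = pd.read_csv(path, comment="#")
    if "t_sec" not in df.columns:
        raise ConfigError(f"{path}: beat CSV must have a 't_sec' column")
    return BeatSeries(times=df["t_sec"].to_numpy(dtype=float))


def write_ibi_csv(ibi: IBISeries, path: str | Path, tag: str = "dyadsync") -> None:
    df = pd.DataFrame({"t_sec": ibi.times, "ibi_ms": ibi.ibi})
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w") as fh:
        fh.write(_header(tag))
        for a, b in ibi.missing_segments:
            fh.write(f"# missing_segment {a} {b}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_ibi_csv(path: str | Path) -> IBISeries:
    segments = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# missing_segment"):
                _, _, a, b = line.split()
                segments.append((float(a), float(b)))
            elif not line.startswith("#"):
                break
    df = pd.read_csv(path, comment="#")
    return IBISeries(
        times=df["t_sec"].to_numpy(dtype=float),
        ibi=df["ibi_ms"].to_numpy(dtype=float),
        missing_segments=tuple(segments),
    )


def write_rsa_csv(
    rsa: RSASeries,
    path: str | Path,
    dyad_id: str,
    task: str,
    role: str,
    tag: str = "dyadsync",
) -> None:
    df = pd.DataFrame(
        {
            "dyad_id": dyad_id,
            "task": task,
            "role": role,
            "t_sec": rsa.seconds,
            "rsa_ln_ms2": rsa.values,
            "valid": rsa.valid_mask.astype(int),
        }
    )
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w") as fh:
        fh.write(_header(tag))
        fh.write(f"# band {rsa.band.low} {rsa.band.high} {rsa.band.label}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_rsa_csv(path: str | Path) -> tuple[RSASeries, dict]:
    band = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# band"):
                _, _, lo, hi, label = line.split()
                band = BandSpec(float(lo), float(hi), label)
            elif not line.startswith("#"):
                break
    if band is None:
        raise ConfigError(f"{path}: RSA CSV is missing its band header")
    df = pd.read_csv(path, comment="#")
    rsa = RSASeries(
        seconds=df["t_sec"].to_numpy(dtype=int),
        values=df["rsa_ln_ms2"].to_numpy(dtype=float),
        valid_mask=df["valid"].to_numpy(dtype=bool),
        band=band,
    )
    meta = {
        "dyad_id": str(df["dyad_id"].iloc[0]),
        "task": str(df["task"].iloc[0]),
        "role": str(df["role"].iloc[0]),
    }
    return rsa, meta


def write_manifest(entries: list[dict], path: str | Path, tag: str, seed: int) -> None:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    payload = {"config_hash": tag, "seed": seed, "records": entries}
    with open(p, "w") as fh:
        json.dump(payload, fh, indent=1, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_posteriors_csv(posteriors: list[VARPosterior], path: str | Path, tag: str) -> None:
    rows = []
    for post in posteriors:
        for name in PARAM_NAMES:
            s = post.params[name]
            rows.append(
                {
                    "dyad_id": post.dyad_id,
                    "task": post.task,
                    "parameter": name,
                    "median": s.median,
                    "cri_low": s.cri_low,
                    "cri_high": s.cri_high,
                    "psr": s.psr,
                    "converged": int(post.converged),
                    "discarded_fraction": post.discarded_fraction,
                    "n_iterations": post.n_iterations_used,
                }
            )
    _write_df(pd.DataFrame(rows), Path(path), tag)


def write_screening_csv(
    screens: list[tuple[str, str, DyadScreen]], path: str | Path, tag: str
) -> None:
    rows = []
    for dyad_id, task, screen in screens:
        for role, results, meets in (
            ("parent", screen.parent_results, screen.parent_meets_stationarity),
            ("child", screen.child_results, screen.child_meets_stationarity),
        ):
            mean_res, trend_res = results
            rows.append(
                {
                    "dyad_id": dyad_id,
                    "task": task,
                    "role": role,
                    "adf_stat_mean": mean_res.statistic,
                    "p_mean": mean_res.p_value,
                    "adf_stat_trend": trend_res.statistic,
                    "p_trend": trend_res.p_value,
                    "meets_stationarity": int(meets),
                }
            )
    _write_df(pd.DataFrame(rows), Path(path), tag)


def write_calls_csv(calls: list[SynchronyCall], path: str | Path, tag: str) -> None:
    df = pd.DataFrame(
        {
            "dyad_id": [c.dyad_id for c in calls],
            "task": [c.task for c in calls],
            "parent_driven": [c.parent_driven for c in calls],
            "child_driven": [c.child_driven for c in calls],
            "converged": [int(c.converged) for c in calls],
        }
    )
    _write_df(df, Path(path), tag)


def read_calls_csv(path: str | Path) -> list[SynchronyCall]:
    # keep_default_na: the category literal "null" must stay a string
    df = pd.read_csv(path, comment="#", keep_default_na=False)
    return [
        SynchronyCall(
            dyad_id=str(r.dyad_id),
            task=str(r.task),
            parent_driven=str(r.parent_driven),
            child_driven=str(r.child_driven),
            converged=bool(r.converged),
        )
        for r in df.itertuples()
    ]


def write_agreement_json(table, counts, path: str | Path, tag: str, seed: int) -> None:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "config_hash": tag,
        "seed": seed,
        "n_task1": table.n_task1,
        "n_task2": table.n_task2,
        "n_both": table.n_both,
        "analyzable": {"per_task": counts.per_task, "n_both": counts.n_both},
        "rows": table.rows.to_dict(orient="records"),
    }
    with open(p, "w") as fh:
        json.dump(payload, fh, indent=1, default=_json_default)
        fh.write("\n")
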