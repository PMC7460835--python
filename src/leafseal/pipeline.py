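"""Orchestration: simulate -> contract -> compare -> tables -> report.

Each stage exchanges tidy CSV under ``<out>/<stage>/`` so every stage is
independently testable and re-runnable; outputs carry provenance columns
(run id, seed, config hash).  All randomness flows from the single seed
in :class:`RunConfig`, so re-running with an identical config is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, DataError, LeafSealError
from .kinematics import (
    DEFAULT_SEGMENTS,
    ContractionSeries,
    MarkerTrack,
    SegmentDefinition,
    endpoint_summary,
)
from .stats import (
    FactorialDataset,
    pairwise_wilcoxon,
    scheirer_ray_hare,
    significance_stars,
)
from .biomechanics import comparison_table, nilsson_parenchyma_modulus
from .reference import (
    CELL_WALL_MODULUS_MPA,
    MECHANICAL_PROPERTIES,
    PARENCHYMA_INPUTS,
)

__all__ = ["RunConfig", "run", "STAGES"]

STAGES = ("simulate", "contract", "compare", "tables", "report")


class StageError(LeafSealError):
    """A pipeline stage failed; the stage name is recorded."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible pipeline run depends on."""

    out_dir: str = "run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    n_leaves_per_group: int = 10
    mode_by_species: Mapping[str, str] = field(
        default_factory=lambda: {"D. cooperi": "y_spacing",
                                 "D. ecklonis": "arc"}
    )
    degree: int = 3
    endpoint_window: int = 5
    posthoc: str = "bonferroni"
    duration_min: float = 60.0
    format_version: str = "1"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")
        if self.degree < 1:
            raise ConfigError("degree must be >= 1")
        if self.endpoint_window < 1:
            raise ConfigError("endpoint_window must be >= 1")
        if self.duration_min <= 0:
            raise ConfigError("duration_min must be positive")
        for sp, mode in self.mode_by_species.items():
            if mode not in ("arc", "y_spacing"):
                raise ConfigError(f"unknown mode {mode!r} for {sp!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mode_by_species"] = dict(self.mode_by_species)
        d["stages"] = list(self.stages)
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @property
    def run_id(self) -> str:
        return f"run-{self.config_hash}-s{self.seed}"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _provenance(df: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["run_id"] = cfg.run_id
    df["seed"] = cfg.seed
    df["config_hash"] = cfg.config_hash
    return df


def _stage_simulate(cfg: RunConfig, out: Path) -> None:
    from .synthetic import SPECIES_TEMPLATES, CohortConfig, simulate_cohort

    tracks_dir = out / "simulate" / "tracks"
    tracks_dir.mkdir(parents=True, exist_ok=True)
    templates = {
        sp: replace(tpl, duration_min=cfg.duration_min)
        for sp, tpl in SPECIES_TEMPLATES.items()
    }
    cohort = simulate_cohort(
        CohortConfig(n_leaves_per_group=cfg.n_leaves_per_group,
                     templates=templates, seed=cfg.seed)
    )
    records = []
    for i, (track, species, rh) in enumerate(cohort):
        leaf_id = f"leaf_{i:03d}"
        fname = f"{leaf_id}.csv"
        track.write_csv(tracks_dir / fname)
        records.append({"leaf_id": leaf_id, "species": species,
                        "rh": rh, "file": fname})
    manifest = _provenance(pd.DataFrame(records), cfg)
    manifest.to_csv(out / "simulate" / "manifest.csv", index=False)


def _stage_contract(cfg: RunConfig, out: Path) -> None:
    manifest_path = out / "simulate" / "manifest.csv"
    if not manifest_path.exists():
        raise DataError(f"missing intermediate {manifest_path}; "
                        "run the simulate stage first")
    manifest = pd.read_csv(manifest_path)
    contract_dir = out / "contract"
    contract_dir.mkdir(parents=True, exist_ok=True)

    tidy_parts, endpoint_rows = [], []
    for row in manifest.itertuples(index=False):
        track = MarkerTrack.read_csv(out / "simulate" / "tracks" / row.file)
        mode = cfg.mode_by_species.get(row.species, "arc")
        series = ContractionSeries.from_track(
            track, DEFAULT_SEGMENTS, mode=mode, degree=cfg.degree
        )
        tidy = series.to_frame(leaf_id=row.leaf_id)
        tidy["species"] = row.species
        tidy["rh"] = row.rh
        tidy_parts.append(tidy)
        eps_hat = endpoint_summary(series, cfg.endpoint_window)
        eps_rel_hat = endpoint_summary(series, cfg.endpoint_window,
                                       which="eps_rel")
        for seg, val in eps_hat.items():
            endpoint_rows.append({
                "leaf_id": row.leaf_id, "species": row.species,
                "rh": row.rh, "segment": seg,
                "eps_abs": val, "eps_rel": eps_rel_hat[seg],
            })
    contractions = _provenance(pd.concat(tidy_parts, ignore_index=True), cfg)
    contractions.to_csv(contract_dir / "contractions.csv", index=False)
    endpoints = _provenance(pd.DataFrame(endpoint_rows), cfg)
    endpoints.to_csv(contract_dir / "endpoints.csv", index=False)


def _stage_compare(cfg: RunConfig, out: Path) -> None:
    endpoints_path = out / "contract" / "endpoints.csv"
    if not endpoints_path.exists():
        raise DataError(f"missing intermediate {endpoints_path}; "
                        "run the contract stage first")
    endpoints = pd.read_csv(endpoints_path)
    compare_dir = out / "compare"
    compare_dir.mkdir(parents=True, exist_ok=True)

    srh_rows, pw_rows = [], []
    for rh, sub in endpoints.groupby("rh", sort=False):
        data = FactorialDataset.from_frame(
            sub, response="eps_abs", factors=["segment", "species"]
        )
        res = scheirer_ray_hare(data)
        for effect, e in res.effects.items():
            name = {"A": "segment", "B": "species",
                    "AB": "segment:species"}[effect]
            srh_rows.append({
                "rh": rh, "effect": name, "df": e.df, "H": e.H,
                "p_chi2": e.p_chi2, "F": e.F, "df_denom": e.df_denom,
                "p_F": e.p_F, "stars": significance_stars(e.p_chi2),
            })
        groups = {
            f"{sp}:{seg}": g["eps_abs"].to_numpy()
            for (sp, seg), g in sub.groupby(["species", "segment"],
                                            sort=False)
        }
        for comp in pairwise_wilcoxon(groups, adjust=cfg.posthoc):
            pw_rows.append({
                "rh": rh, "group_1": comp.group_1, "group_2": comp.group_2,
                "U": comp.U, "p_raw": comp.p_raw,
                "p_adjusted": comp.p_adjusted, "stars": comp.stars,
                "method": comp.method,
            })
    _provenance(pd.DataFrame(srh_rows), cfg).to_csv(
        compare_dir / "srh.csv", index=False)
    _provenance(pd.DataFrame(pw_rows), cfg).to_csv(
        compare_dir / "pairwise.csv", index=False)


def _stage_tables(cfg: RunConfig, out: Path) -> None:
    tables_dir = out / "tables"
    tables_dir.mkdir(parents=True, exist_ok=True)
    comp = comparison_table(MECHANICAL_PROPERTIES)
    _provenance(comp, cfg).to_csv(tables_dir / "comparison.csv", index=False)

    rows = []
    for (species, tissue), inp in PARENCHYMA_INPUTS.items():
        E = nilsson_parenchyma_modulus(
            inp["cell"], inp["P_mpa"], inp["nu"], CELL_WALL_MODULUS_MPA
        )
        rows.append({
            "species": species, "tissue": tissue,
            "d_c_um": inp["cell"].d_c_um, "t_cw_um": inp["cell"].t_cw_um,
            "P_mpa": inp["P_mpa"], "nu": inp["nu"],
            "E_mpa": round(E, 4),
        })
    _provenance(pd.DataFrame(rows), cfg).to_csv(
        tables_dir / "parenchyma_moduli.csv", index=False)


def _stage_report(cfg: RunConfig, out: Path) -> None:
    report_dir = out / "report"
    report_dir.mkdir(parents=True, exist_ok=True)

    summary: dict = {
        "run_id": cfg.run_id,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash,
        "format_version": cfg.format_version,
        "versions": {
            "leafseal": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": cfg.to_dict(),
    }

    endpoints_path = out / "contract" / "endpoints.csv"
    if endpoints_path.exists():
        endpoints = pd.read_csv(endpoints_path)
        med = (endpoints.groupby(["species", "rh", "segment"])["eps_abs"]
               .median())
        summary["median_endpoint_contraction"] = {
            " | ".join(k): round(v, 5) for k, v in med.items()
        }
    for stage, fname in (("compare", "srh.csv"),
                         ("tables", "comparison.csv"),
                         ("tables", "parenchyma_moduli.csv")):
        path = out / stage / fname
        if path.exists():
            df = pd.read_csv(path)
            summary[fname.removesuffix(".csv")] = df.drop(
                columns=["run_id", "seed", "config_hash"], errors="ignore"
            ).to_dict(orient="records")

    with open(report_dir / "report.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    with open(report_dir / "log.json", "w") as fh:
        json.dump({"run_id": cfg.run_id, "seed": cfg.seed,
                   "config": cfg.to_dict(),
                   "config_hash": cfg.config_hash,
                   "versions": summary["versions"]}, fh, indent=2)

    contractions_path = out / "contract" / "contractions.csv"
    if contractions_path.exists():
        _plot_medians(pd.read_csv(contractions_path),
                      report_dir / "contraction_medians.png")


def _plot_medians(contractions: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    segments = list(dict.fromkeys(contractions["segment"]))
    fig, axes = plt.subplots(1, len(segments), figsize=(4 * len(segments), 3),
                             sharey=True)
    axes = np.atleast_1d(axes)
    for ax, seg in zip(axes, segments):
        sub = contractions[contractions["segment"] == seg]
        for (sp, rh), g in sub.groupby(["species", "rh"], sort=False):
            med = g.groupby("time_s")["eps_abs"].median()
            ax.plot(med.index / 60.0, med.values, label=f"{sp}, {rh}")
        ax.set_title(seg)
        ax.set_xlabel("time (min)")
    axes[0].set_ylabel("absolute contraction")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "contract": _stage_contract,
    "compare": _stage_compare,
    "tables": _stage_tables,
    "report": _stage_report,
}


def run(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    The verbatim config is serialized into the output directory before
    any stage runs.  A stage failure aborts the run with the failing
    stage named; stages after the failure are not attempted.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)

    for stage in STAGES:
        if stage not in config.stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, out)
        except LeafSealError:
            raise
        except Exception as exc:  # noqa: BLE001 - named-stage contract
            raise StageError(stage, exc) from exc
    return out
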