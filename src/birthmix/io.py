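"""File formats: record CSVs, fitted-model JSON, scenario YAML, curve
export.

Records travel as CSV with a header row and columns ``birthweight_g``,
``death`` and optionally ``covariate``; malformed rows are rejected with
a per-row report rather than silently dropped.  Fitted models round-trip
through JSON; scenario specifications through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .mixture import MixtureModel
from .records import BIRTHWEIGHT, COVARIATE, DEATH, validate_records
from .risk import RiskModel, curve_support
from .simulate import ScenarioSpec

logger = logging.getLogger("birthmix")

PathLike = Union[str, Path]


@dataclasses.dataclass(frozen=True)
class ReadReport:
    """Outcome of reading a record CSV: the valid rows plus a per-row
    account of the rejects."""

    records: pd.DataFrame
    n_read: int
    rejected: pd.DataFrame  # columns: row, reason

    @property
    def n_kept(self) -> int:
        return len(self.records)


def read_records(path: PathLike) -> ReadReport:
    """Read birth records from CSV (header required).

    Rows with missing or nonpositive birthweight, or a non-binary death
    indicator (or covariate, when the column is present), are rejected
    and itemized in the report; an error is raised only if the file is
    unreadable or no valid row remains.
    """
    raw = pd.read_csv(path, comment="#")
    for col in (BIRTHWEIGHT, DEATH):
        if col not in raw.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    reasons: List[dict] = []
    bw = pd.to_numeric(raw[BIRTHWEIGHT], errors="coerce")
    death = pd.to_numeric(raw[DEATH], errors="coerce")
    bad_bw = ~np.isfinite(bw) | (bw <= 0)
    bad_death = ~death.isin([0, 1])
    bad = bad_bw | bad_death
    if COVARIATE in raw.columns:
        cov = pd.to_numeric(raw[COVARIATE], errors="coerce")
        bad_cov = cov.notna() & ~cov.isin([0, 1])
        bad |= bad_cov
    for i in raw.index[bad]:
        if bad_bw[i]:
            reason = f"invalid birthweight {raw.loc[i, BIRTHWEIGHT]!r}"
        elif bad_death[i]:
            reason = f"invalid death indicator {raw.loc[i, DEATH]!r}"
        else:
            reason = f"invalid covariate {raw.loc[i, COVARIATE]!r}"
        reasons.append({"row": int(i), "reason": reason})
    kept = raw[~bad].copy()
    kept[BIRTHWEIGHT] = bw[~bad]
    kept[DEATH] = death[~bad].astype(int)
    if len(kept) == 0:
        raise ValueError(f"{path}: no valid rows")
    logger.info("read %s: kept %d rows, rejected %d", path, len(kept), int(bad.sum()))
    validate_records(kept)
    return ReadReport(
        records=kept.reset_index(drop=True),
        n_read=len(raw),
        rejected=pd.DataFrame(reasons, columns=["row", "reason"]),
    )


def write_records(records: pd.DataFrame, path: PathLike) -> None:
    validate_records(records)
    records.to_csv(path, index=False)


def mixture_to_dict(model: MixtureModel) -> dict:
    return {
        "k": model.k,
        "weights": model.weights.tolist(),
        "means_g": model.means.tolist(),
        "sds_g": model.sds.tolist(),
        "loglik": model.loglik,
        "converged": model.converged,
    }


def mixture_from_dict(d: dict) -> MixtureModel:
    return MixtureModel(
        weights=np.asarray(d["weights"], dtype=float),
        means=np.asarray(d["means_g"], dtype=float),
        sds=np.asarray(d["sds_g"], dtype=float),
        loglik=d.get("loglik"),
        converged=d.get("converged", True),
    )


def save_mixture(model: MixtureModel, path: PathLike) -> None:
    Path(path).write_text(json.dumps(mixture_to_dict(model), indent=2))


def load_mixture(path: PathLike) -> MixtureModel:
    return mixture_from_dict(json.loads(Path(path).read_text()))


def risk_to_dict(risk: RiskModel) -> dict:
    return {
        "degree": risk.degree,
        "z_convention": "component_standardized",
        "coeffs": [
            None if not ok else row.tolist()
            for ok, row in zip(risk.estimable, risk.coeffs)
        ],
        "loglik": risk.loglik,
        "converged": risk.converged,
        "mixture": mixture_to_dict(risk.mixture),
    }


def risk_from_dict(d: dict) -> RiskModel:
    mixture = mixture_from_dict(d["mixture"])
    ncoef = d["degree"] + 1
    coeffs = np.array(
        [row if row is not None else [np.nan] * ncoef for row in d["coeffs"]],
        dtype=float,
    )
    return RiskModel(
        mixture=mixture,
        coeffs=coeffs,
        degree=d["degree"],
        loglik=d.get("loglik"),
        converged=d.get("converged", True),
    )


def save_risk(risk: RiskModel, path: PathLike) -> None:
    Path(path).write_text(json.dumps(risk_to_dict(risk), indent=2))


def load_risk(path: PathLike) -> RiskModel:
    return risk_from_dict(json.loads(Path(path).read_text()))


def scenario_to_dict(spec: ScenarioSpec) -> dict:
    return {
        "mixture": mixture_to_dict(spec.mixture),
        "risk": risk_to_dict(spec.risk),
        "population_size": spec.population_size,
        "n": spec.n,
        "n_rep": spec.n_rep,
        "seed": spec.seed,
    }


def save_scenario(spec: ScenarioSpec, path: PathLike) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(spec), sort_keys=False))


def load_scenario(path: PathLike) -> ScenarioSpec:
    d = yaml.safe_load(Path(path).read_text())
    return ScenarioSpec(
        mixture=mixture_from_dict(d["mixture"]),
        risk=risk_from_dict(d["risk"]),
        population_size=d.get("population_size"),
        n=d["n"],
        n_rep=d["n_rep"],
        seed=d.get("seed", 0),
    )


def export_curves(
    risk: RiskModel,
    grid: Optional[Sequence[float]] = None,
    support_c: float = 3.0,
) -> pd.DataFrame:
    """Tabulate the fitted component curves on a birthweight grid
    (default 250-5500 g step 10), with a flag marking whether each point
    lies inside the component's reported support (mu_j +/- 3 sigma_j)."""
    if grid is None:
        grid = np.arange(250.0, 5501.0, 10.0)
    grid = np.asarray(grid, dtype=float)
    frames = []
    for j in range(1, risk.k + 1):
        if not risk.estimable[j - 1]:
            continue
        lo, hi = curve_support(risk.mixture, j, support_c)
        frames.append(
            pd.DataFrame(
                {
                    "birthweight_g": grid,
                    "component": j,
                    "risk": np.atleast_1d(risk.component_risk(j, grid)),
                    "in_support": (grid >= lo) & (grid <= hi),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for stamping
    outputs so that identical runs are recognizably identical."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_stamped_csv(frame: pd.DataFrame, path: PathLike, config: dict) -> None:
    """Write a CSV preceded by comment lines embedding the config hash
    and the seed, so reruns with identical inputs are byte-identical."""
    header = f"# config_hash={config_hash(config)}\n# seed={config.get('seed')}\n"
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, index=False, float_format="%.10g")
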