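"""Per-structure feature table and correlation with temperature optimum.

Aggregates the interaction, helix and compactness detectors into one row per
structure, attaches the activity temperature optimum (degrees C) and reports
the Pearson correlation coefficient of every feature with the optimum, both
over all structures and with an exclusion set removed (used when one
structure's optimum is only an assumption, e.g. a gut-niche organism
assigned 37 degrees C).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import compactness as _compactness
from . import helix_composition as _helix
from . import interactions as _interactions
from .structure_io import StructureModel

__all__ = [
    "DEFAULT_TEMPERATURE_OPTIMA",
    "DEFAULT_CONFIG",
    "CorrelationResult",
    "build_feature_table",
    "pearson_r",
    "correlate_features",
]

#: Activity temperature optima (degrees C) of the structurally characterized
#: GH53 galactanases, keyed by PDB entry. The hyperthermophilic archaeal
#: enzyme is reported as "at least 95"; the gut bacterium's optimum is an
#: assumption from its niche (37) and is conventionally excluded in a
#: sensitivity pass.
DEFAULT_TEMPERATURE_OPTIMA: dict[str, float] = {
    "7OSK": 95.0,  # IaGal (archaeal, hyperthermostable)
    "1R8L": 40.0,  # BlGal
    "6GP5": 37.0,  # BtGal (assumed from niche)
    "1FOB": 50.0,  # AaGal
    "4BF7": 49.0,  # EnGal
    "1HJQ": 65.0,  # HiGal
    "1HJS": 65.0,  # MtGal
}

FEATURE_COLUMNS = [
    "salt_bridges",
    "hbonds",
    "pi_pi",
    "cation_pi",
    "disulfides",
    "stabilized_helices",
    "dipole_net",
    "pro_gly_ratio",
    "sasa",
    "total_volume",
    "packing_density",
    "surface_to_volume",
]

DEFAULT_CONFIG: dict = {
    "salt_bridge_cutoff": 4.0,
    "hbond_cutoff": 3.5,
    "pi_pi_cutoff": 7.2,
    "cation_pi_dist_cutoff": 6.0,
    "cation_pi_angle_cutoff": 60.0,
    "disulfide_cutoff": 2.5,
    "sasa_probe": 1.4,
    "sasa_n_points": 960,
    "grid_spacing": 0.5,
    "helix_source": "auto",  # records when present, else dihedral
    "compute_compactness": True,
}


@dataclass
class CorrelationResult:
    """Pearson r of one feature against the temperature optimum."""

    feature: str
    r_with: float
    r_without: float
    n_with: int
    n_without: int


def _structure_features(model: StructureModel, config: dict) -> dict[str, float]:
    row: dict[str, float] = {}
    row["salt_bridges"] = len(
        _interactions.detect_salt_bridges(model, cutoff=config["salt_bridge_cutoff"])
    )
    row["hbonds"] = len(_interactions.detect_hydrogen_bonds(model, cutoff=config["hbond_cutoff"]))
    row["pi_pi"] = len(_interactions.detect_pi_pi(model, cutoff=config["pi_pi_cutoff"]))
    row["cation_pi"] = len(
        _interactions.detect_cation_pi(
            model,
            dist_cutoff=config["cation_pi_dist_cutoff"],
            angle_cutoff=config["cation_pi_angle_cutoff"],
        )
    )
    row["disulfides"] = len(
        _interactions.detect_disulfides(model, cutoff=config["disulfide_cutoff"])
    )
    source = config["helix_source"]
    if source == "auto":
        source = "records" if model.helix_annotations else "dihedral"
    try:
        helices = _helix.assign_helices(model, source=source)
    except ValueError:
        helices = []
    score = _helix.score_helix_dipoles(model, helices)
    row["stabilized_helices"] = score.n_stabilized_helices
    row["dipole_net"] = score.net
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        row["pro_gly_ratio"] = _helix.pro_gly_ratio(model)
    if config.get("compute_compactness", True):
        metrics = _compactness.compactness_metrics(
            model,
            probe=config["sasa_probe"],
            n_points=config["sasa_n_points"],
            grid_spacing=config["grid_spacing"],
        )
        row["sasa"] = metrics.sasa
        row["total_volume"] = metrics.total_volume
        row["packing_density"] = metrics.packing_density
        row["surface_to_volume"] = metrics.surface_to_volume
    else:
        row["sasa"] = row["total_volume"] = math.nan
        row["packing_density"] = row["surface_to_volume"] = math.nan
    return row


def build_feature_table(
    models: list[StructureModel],
    phenotypes: dict[str, float],
    config: dict | None = None,
) -> pd.DataFrame:
    """One feature row per structure plus the ``t_opt`` phenotype column.

    Every model must have a phenotype entry (temperature optimum, degrees C).
    """
    if not models:
        raise ValueError("no structures provided")
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    rows = {}
    for model in models:
        sid = model.structure_id
        if sid not in phenotypes:
            raise KeyError(f"no temperature optimum for structure {sid!r}")
        row = _structure_features(model, cfg)
        row["t_opt"] = float(phenotypes[sid])
        rows[sid] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "structure_id"
    return table[FEATURE_COLUMNS + ["t_opt"]]


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient; NaN for zero-variance input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def correlate_features(
    table: pd.DataFrame, exclude: set[str] | None = None
) -> list[CorrelationResult]:
    """Pearson r of every feature with t_opt, with and without ``exclude``.

    Results are sorted by |r_with| descending. The exclusion set must leave
    at least three rows.
    """
    exclude = exclude or set()
    if "t_opt" not in table.columns:
        raise ValueError("feature table lacks a t_opt column")
    sub = table.drop(index=[i for i in exclude if i in table.index])
    if len(sub) < 3:
        raise ValueError(
            f"excluding {sorted(exclude)} leaves {len(sub)} rows; need at least 3"
        )
    results = []
    for feature in (c for c in table.columns if c != "t_opt"):
        x_all = table[feature].to_numpy(dtype=float)
        keep_all = np.isfinite(x_all)
        x_sub = sub[feature].to_numpy(dtype=float)
        keep_sub = np.isfinite(x_sub)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r_with = (
                pearson_r(x_all[keep_all], table["t_opt"].to_numpy()[keep_all])
                if keep_all.sum() >= 3
                else float("nan")
            )
            r_without = (
                pearson_r(x_sub[keep_sub], sub["t_opt"].to_numpy()[keep_sub])
                if keep_sub.sum() >= 3
                else float("nan")
            )
        results.append(
            CorrelationResult(
                feature=feature,
                r_with=r_with,
                r_without=r_without,
                n_with=int(keep_all.sum()),
                n_without=int(keep_sub.sum()),
            )
        )
    results.sort(key=lambda r: (-(abs(r.r_with) if math.isfinite(r.r_with) else -1.0), r.feature))
    return results
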