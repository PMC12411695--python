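"""File contracts: manifests, tables, design bundles, posterior archives.

Input tables are delimited text (CSV) with sites as rows and species as
columns, missing cells empty or NA; a manifest (YAML or JSON) names the
abundance file, one file per trait, the covariate file and the assembly
options.  Outputs are CSV tables plus a JSON run-manifest recording seeds,
prior hyperparameters and MCMC settings, and round-trip numerically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import (
    EnvironmentalDesign,
    ModelDesign,
    MultiResponseMatrix,
    SpeciesTraitMatrix,
    expand_trait_design,
)
from .responses import ResponseType, case_study_rtypes
from .sampler import PosteriorSampleSet

__all__ = [
    "read_manifest",
    "read_inputs",
    "write_outputs",
    "save_samples",
    "load_samples",
    "save_design",
    "load_design",
]


def read_manifest(path) -> dict:
    """Load a YAML/JSON manifest describing the input files and options."""
    path = Path(path)
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "files" not in manifest:
        raise ValueError(f"manifest {path} must contain a 'files' mapping")
    files = manifest["files"]
    if "abundance" not in files:
        raise ValueError(f"manifest {path} is missing files.abundance")
    manifest.setdefault("_base_dir", str(path.parent))
    return manifest


def _read_table(path, what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"{what} table not found: {path}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{what} table {path} has no data columns")
    return df


def read_inputs(manifest: dict):
    """Read (abundance, trait_tables, covariates, rtypes, options) per manifest."""
    base = Path(manifest.get("_base_dir", "."))
    files = manifest["files"]
    abundance = _read_table(base / files["abundance"], "abundance")
    trait_tables = {
        name: _read_table(base / p, f"trait {name!r}")
        for name, p in files.get("traits", {}).items()
    }
    covariates = (
        _read_table(base / files["covariates"], "covariate")
        if "covariates" in files
        else None
    )
    if "response_types" in manifest:
        rtypes = [ResponseType(**rt) for rt in manifest["response_types"]]
    else:
        rtypes = case_study_rtypes(tuple(trait_tables))
    options = {
        "min_prevalence": int(manifest.get("min_prevalence", 0)),
        "scale_responses": bool(manifest.get("scaling", {}).get("responses", True)),
        "scale_covariates": bool(manifest.get("scaling", {}).get("covariates", True)),
    }
    return abundance, trait_tables, covariates, rtypes, options


def write_outputs(tables: dict[str, pd.DataFrame], out_dir, run_manifest: dict | None = None):
    """Write result tables as CSV plus a JSON run-manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv", float_format="%.17g")
    if run_manifest is not None:
        with open(out_dir / "run_manifest.json", "w") as fh:
            json.dump(run_manifest, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# posterior archives
# ---------------------------------------------------------------------------
def save_samples(samples: PosteriorSampleSet, path) -> None:
    arrays = {
        k: getattr(samples, k)
        for k in ("beta", "gamma", "V", "Lambda", "sigma2")
    }
    if samples.H is not None:
        arrays["H"] = samples.H
    np.savez_compressed(path, meta=json.dumps(samples.meta), **arrays)


def load_samples(path) -> PosteriorSampleSet:
    with np.load(path, allow_pickle=False) as z:
        return PosteriorSampleSet(
            beta=z["beta"],
            gamma=z["gamma"],
            V=z["V"],
            Lambda=z["Lambda"],
            sigma2=z["sigma2"],
            H=z["H"] if "H" in z.files else None,
            meta=json.loads(str(z["meta"])),
        )


# ---------------------------------------------------------------------------
# serialized model-design bundle
# ---------------------------------------------------------------------------
def save_design(design: ModelDesign, out_dir) -> None:
    """Serialize a model design as CSV tables plus JSON metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    Y = design.Y
    cols = Y.column_labels
    pd.DataFrame(Y.values, index=Y.site_ids, columns=cols).to_csv(
        out_dir / "y_values.csv", float_format="%.17g"
    )
    pd.DataFrame(Y.observed.astype(int), index=Y.site_ids, columns=cols).to_csv(
        out_dir / "y_observed.csv"
    )
    pd.DataFrame(
        design.env.X,
        index=Y.site_ids,
        columns=["intercept"] + list(design.env.covariate_names),
    ).to_csv(out_dir / "x_design.csv")
    pd.DataFrame(
        design.traits.T,
        index=design.traits.species,
        columns=["intercept"] + list(design.traits.trait_names),
    ).to_csv(out_dir / "t_species.csv")
    meta = {
        "rtypes": [
            {"name": r.name, "family": r.family, "transform": r.transform, "role": r.role}
            for r in Y.rtypes
        ],
        "species": Y.species,
        "col_center": Y.col_center.tolist(),
        "col_scale": Y.col_scale.tolist(),
        "env_center": design.env.center.tolist(),
        "env_scale": design.env.scale.tolist(),
        "trait_center": design.traits.center.tolist(),
        "trait_scale": design.traits.scale.tolist(),
        "trait_provenance": design.traits.provenance,
    }
    with open(out_dir / "design_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_design(in_dir) -> ModelDesign:
    in_dir = Path(in_dir)
    with open(in_dir / "design_meta.json") as fh:
        meta = json.load(fh)
    rtypes = [ResponseType(**rt) for rt in meta["rtypes"]]
    yv = pd.read_csv(in_dir / "y_values.csv", index_col=0, float_precision="round_trip")
    yo = pd.read_csv(in_dir / "y_observed.csv", index_col=0)
    xd = pd.read_csv(in_dir / "x_design.csv", index_col=0, float_precision="round_trip")
    td = pd.read_csv(in_dir / "t_species.csv", index_col=0, float_precision="round_trip")
    Y = MultiResponseMatrix(
        yv.to_numpy(dtype=float),
        yo.to_numpy(dtype=bool),
        list(yv.index),
        meta["species"],
        rtypes,
        np.asarray(meta["col_center"], dtype=float),
        np.asarray(meta["col_scale"], dtype=float),
    )
    env = EnvironmentalDesign(
        xd.to_numpy(dtype=float),
        list(xd.columns[1:]),
        list(xd.index),
        np.asarray(meta["env_center"], dtype=float),
        np.asarray(meta["env_scale"], dtype=float),
    )
    traits = SpeciesTraitMatrix(
        td.to_numpy(dtype=float),
        list(td.columns[1:]),
        list(td.index),
        meta["trait_provenance"],
        np.asarray(meta["trait_center"], dtype=float),
        np.asarray(meta["trait_scale"], dtype=float),
    )
    return ModelDesign(Y, env, traits, expand_trait_design(traits, rtypes))
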