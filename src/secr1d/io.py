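"""Plain-text readers and writers for the pipeline's tables.

All interchange formats are delimited text with headers: sightings
(``individual_id,date,latitude``, ISO-8601 dates, decimal degrees), daily
effort (``date,bin_index,area_km2``), ground truth
(``individual_id,year,C_true,sigma2_true,R_true,A_true``), static stressor
layers (``bin_index,value``), dynamic layers
(``bin_index,year,month,value``), and the posterior as a long table
(``chain,draw,parameter,value``) where per-individual-year parameters are
labelled ``name[individual,year]``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .encounters import EncounterArray
from .exposure import StressorLayer
from .model import ModelConfig, PosteriorSamples, PriorSpec

_FLOAT_FMT = "%.12g"


def write_sightings(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format=_FLOAT_FMT,
               columns=["individual_id", "date", "latitude"])


def read_sightings(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"individual_id": str})
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_effort(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format=_FLOAT_FMT,
               columns=["date", "bin_index", "area_km2"])


def read_effort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"])
    return df


def write_truth(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT,
              columns=["individual_id", "year", "C_true", "sigma2_true",
                       "R_true", "A_true"])


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"individual_id": str})


def write_layer(layer: StressorLayer, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if layer.kind == "static":
        path = directory / f"{layer.name}.static.csv"
        pd.DataFrame({"bin_index": np.arange(1, len(layer.values) + 1),
                      "value": layer.values}).to_csv(path, index=False,
                                                     float_format=_FLOAT_FMT)
    else:
        path = directory / f"{layer.name}.dynamic.csv"
        layer.table.to_csv(path, index=False, float_format=_FLOAT_FMT,
                           columns=["bin_index", "year", "month", "value"])
    return path


def read_layer(path) -> StressorLayer:
    path = Path(path)
    stem = path.name
    if stem.endswith(".static.csv"):
        df = pd.read_csv(path).sort_values("bin_index")
        return StressorLayer(stem[:-len(".static.csv")], "static",
                             values=df["value"].to_numpy())
    if stem.endswith(".dynamic.csv"):
        return StressorLayer(stem[:-len(".dynamic.csv")], "dynamic",
                             table=pd.read_csv(path))
    raise ValueError(f"layer file name must end in .static.csv or .dynamic.csv: {stem}")


def read_layers(directory) -> list[StressorLayer]:
    paths = sorted(Path(directory).glob("*.csv"))
    return [read_layer(p) for p in paths]


def write_encounter_array(enc: EncounterArray, directory) -> None:
    """Write S/effort/inclusion as the three delimited tables of the format."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, ind in enumerate(enc.individuals):
        for l in range(enc.S.shape[1]):
            for t, year in enumerate(enc.years):
                if enc.S[i, l, t]:
                    rows.append((ind, l + 1, year, int(enc.S[i, l, t])))
    pd.DataFrame(rows, columns=["individual_id", "bin_index", "year", "count"]) \
        .to_csv(directory / "S.csv", index=False)
    erows = [(l + 1, year, enc.e[l, t])
             for l in range(enc.e.shape[0]) for t, year in enumerate(enc.years)]
    pd.DataFrame(erows, columns=["bin_index", "year", "area_km2"]) \
        .to_csv(directory / "effort.csv", index=False, float_format=_FLOAT_FMT)
    irows = [(ind, year, int(enc.survey_days[i, t]), bool(enc.included[i, t]))
             for i, ind in enumerate(enc.individuals)
             for t, year in enumerate(enc.years)]
    pd.DataFrame(irows, columns=["individual_id", "year", "survey_days", "included"]) \
        .to_csv(directory / "inclusion.csv", index=False)


def read_encounter_array(directory, n_bins: int, min_days: int = 5) -> EncounterArray:
    directory = Path(directory)
    S_long = pd.read_csv(directory / "S.csv", dtype={"individual_id": str})
    e_long = pd.read_csv(directory / "effort.csv")
    inc = pd.read_csv(directory / "inclusion.csv", dtype={"individual_id": str})
    individuals = sorted(inc["individual_id"].unique())
    years = sorted(e_long["year"].unique())
    ind_ix = {v: i for i, v in enumerate(individuals)}
    year_ix = {v: t for t, v in enumerate(years)}
    S = np.zeros((len(individuals), n_bins, len(years)), dtype=int)
    for r in S_long.itertuples(index=False):
        S[ind_ix[r.individual_id], int(r.bin_index) - 1, year_ix[r.year]] = r.count
    e = np.zeros((n_bins, len(years)))
    for r in e_long.itertuples(index=False):
        e[int(r.bin_index) - 1, year_ix[r.year]] = r.area_km2
    survey_days = np.zeros((len(individuals), len(years)), dtype=int)
    included = np.zeros((len(individuals), len(years)), dtype=bool)
    for r in inc.itertuples(index=False):
        survey_days[ind_ix[r.individual_id], year_ix[r.year]] = r.survey_days
        included[ind_ix[r.individual_id], year_ix[r.year]] = r.included
    return EncounterArray(S=S, e=e, survey_days=survey_days, included=included,
                          individuals=individuals, years=years, min_days=min_days)


def write_posterior(samples: PosteriorSamples, directory) -> None:
    """Posterior as ``posterior.csv`` (long format) plus ``manifest.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    samples.to_dataframe().to_csv(directory / "posterior.csv", index=False,
                                  float_format="%.17g")
    cfg = samples.config
    manifest = {
        "individuals": list(samples.individuals),
        "years": [int(y) for y in samples.years],
        "config": {
            "n_chains": cfg.n_chains, "n_iter": cfg.n_iter, "burn_in": cfg.burn_in,
            "thin": cfg.thin, "seed": cfg.seed,
            "absent_center_deg": cfg.absent_center_deg,
            "absent_sigma2": cfg.absent_sigma2,
            "effort_scale_factor": cfg.effort_scale_factor,
            "priors": vars(cfg.priors) if not isinstance(cfg.priors, dict) else cfg.priors,
            "fixed": cfg.fixed,
        },
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                        default=float))


_LABEL_RE = re.compile(r"^(C|sigma2|M|R|A)\[(.+),([^,\]]+)\]$")


def read_posterior(directory) -> PosteriorSamples:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    individuals = manifest["individuals"]
    years = manifest["years"]
    cfg_d = dict(manifest["config"])
    priors = PriorSpec(**cfg_d.pop("priors"))
    cfg = ModelConfig(priors=priors, **{k: v for k, v in cfg_d.items()})
    df = pd.read_csv(directory / "posterior.csv", float_precision="round_trip")
    n_chains = int(df["chain"].max()) + 1
    n_draws = int(df["draw"].max()) + 1
    I, T = len(individuals), len(years)
    ind_ix = {str(v): i for i, v in enumerate(individuals)}
    year_ix = {str(v): t for t, v in enumerate(years)}
    params = {name: np.zeros((n_chains, n_draws, I, T))
              for name in ("C", "sigma2", "M", "R", "A")}
    for name in ("mu", "omega", "beta_e"):
        params[name] = np.zeros((n_chains, n_draws))
    for label, sub in df.groupby("parameter"):
        vals = np.zeros((n_chains, n_draws))
        vals[sub["chain"].to_numpy(int), sub["draw"].to_numpy(int)] = sub["value"].to_numpy()
        m = _LABEL_RE.match(label)
        if m:
            name, ind, year = m.groups()
            params[name][:, :, ind_ix[ind], year_ix[year]] = vals
        else:
            params[label] = vals
    params["A"] = params["A"].astype(int)
    return PosteriorSamples(params=params, individuals=individuals, years=years,
                            config=cfg)
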