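"""CSV/YAML input-output and the end-to-end analysis pipeline.

All tabular data are plain CSV: populations (id, x, y [, radius,
covariate]), diffusion times (id, time [, censored]) and association
matrices (square, ids as header row and column).  Configuration is a
YAML or JSON mapping; every stochastic stage derives its stream from a
single master seed that is recorded, together with a hash of the
configuration, in the run manifest so a rerun reproduces every output
bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import AssociationMatrix, association_matrix
from .inference import bayes_factor_from_counts, posterior_summary, rjmcmc_sample
from .pointpattern import (
    PointPattern,
    Window,
    csr_envelope,
    pair_correlation,
    suggest_interaction_radius,
)
from .simulate import DiffusionRecord, generate_study, normalise_covariate
from .wave import wave_of_advance

__all__ = [
    "RunConfig",
    "read_population",
    "write_population",
    "read_diffusion",
    "write_diffusion",
    "read_association",
    "write_association",
    "write_pcf",
    "load_config",
    "run_pipeline",
]


def read_population(
    path,
    window: Window | None = None,
    default_radius: float | None = None,
    covariate_normalisation: str = "zscore",
):
    """Read a population CSV into a point pattern plus covariates.

    Columns: ``id``, ``x``, ``y``; optional ``radius`` and ``covariate``.
    A missing radius column falls back to ``default_radius`` (leave both
    unset to defer the choice to the exploratory analysis).  Covariates,
    when present, are normalised with the requested method.  The window
    defaults to the unit square.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty population file")
    required = {"id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: population CSV needs columns {sorted(required)}")
    ids = df["id"].tolist()
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate ids")
    try:
        coords = df[["x", "y"]].astype(float).to_numpy()
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric coordinates ({e})") from e
    window = window or Window()
    if not np.all(window.contains(coords)):
        raise ValueError(f"{path}: points outside the observation window")
    radii = None
    if "radius" in df.columns:
        radii = df["radius"].astype(float).to_numpy()
    elif default_radius is not None:
        radii = default_radius
    pattern = PointPattern(ids, coords, radii, window)
    covariates = None
    if "covariate" in df.columns:
        covariates = normalise_covariate(
            df["covariate"].astype(float).to_numpy(), covariate_normalisation
        )
    return pattern, covariates


def write_population(path, pattern: PointPattern, covariates=None, raw_covariates=None):
    data = {"id": pattern.ids, "x": pattern.coords[:, 0], "y": pattern.coords[:, 1]}
    if pattern.radii is not None:
        data["radius"] = pattern.radii
    cov = raw_covariates if raw_covariates is not None else covariates
    if cov is not None:
        data["covariate"] = np.asarray(cov, dtype=float)
    pd.DataFrame(data).to_csv(path, index=False)


def read_diffusion(path, population_ids=None) -> DiffusionRecord:
    """Read diffusion times (id, time [, censored]) keyed to a population."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty diffusion file")
    if not {"id", "time"}.issubset(df.columns):
        raise ValueError(f"{path}: diffusion CSV needs columns id, time")
    ids = df["id"].tolist()
    times = df["time"].astype(float).to_numpy()
    censored = (
        df["censored"].astype(bool).to_numpy()
        if "censored" in df.columns
        else np.zeros(len(ids), dtype=bool)
    )
    if np.any(times < 0):
        raise ValueError(f"{path}: negative times")
    if population_ids is not None:
        if set(ids) != set(population_ids):
            raise ValueError(f"{path}: diffusion ids do not match the population")
        order = {v: k for k, v in enumerate(ids)}
        perm = [order[i] for i in population_ids]
        ids = list(population_ids)
        times, censored = times[perm], censored[perm]
    horizon = float(times.max()) if len(times) else 0.0
    return DiffusionRecord(ids, times, censored, horizon=horizon)


def write_diffusion(path, record: DiffusionRecord):
    pd.DataFrame(
        {
            "id": record.ids,
            "time": record.times,
            "censored": record.censored.astype(int),
        }
    ).to_csv(path, index=False)


def write_association(path, A: AssociationMatrix):
    pd.DataFrame(A.values, index=A.ids, columns=A.ids).to_csv(path)


def read_association(path) -> AssociationMatrix:
    df = pd.read_csv(path, index_col=0)
    return AssociationMatrix(df.to_numpy(dtype=float), list(df.columns))


def write_pcf(path, pcf):
    data = {"r": pcf.r_grid, "g": pcf.g_values, "k": pcf.k_values}
    if pcf.envelope_low is not None:
        data["envelope_low"] = pcf.envelope_low
        data["envelope_high"] = pcf.envelope_high
    data["reliable"] = pcf.reliable.astype(int)
    pd.DataFrame(data).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of an end-to-end run.

    Either ``population`` (a CSV path) or ``simulate`` (keyword arguments
    for :func:`snbda.simulate.generate_study`) provides the input data;
    ``radius`` may be a number or ``"auto"`` to take the pair-correlation
    suggestion.  All stochastic stages derive their streams from
    ``seed``.
    """

    outdir: str = "snbda_run"
    population: str | None = None
    diffusion: str | None = None
    simulate: dict | None = None
    window: tuple = (0.0, 1.0, 0.0, 1.0)
    radius: float | str = "auto"
    normalisation: str = "zscore"
    association_normalisation: str = "receiver"
    models: tuple = (1, 2, 3)
    n_iter: int = 20_000
    burn_in: int = 2_000
    tuning: dict = field(default_factory=dict)
    move_prob: float = 0.5
    n_envelope: int = 99
    r_grid_max: float | None = None
    n_r: int = 50
    seed: int = 0
    run_wave: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = RunConfig(**data)
    if isinstance(cfg.models, (list, tuple)):
        cfg.models = tuple(int(m) for m in cfg.models)
    return cfg


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate/load -> explore -> associations -> fit -> wave.

    Writes every intermediate product (association matrix, pair
    correlation table, radius decision, MCMC trace, posterior summary,
    model probabilities, Bayes factors, wave regression) plus a manifest
    into ``config.outdir`` and returns the result paths and headline
    numbers as a dict.
    """
    bad = [m for m in config.models if m not in (1, 2, 3)]
    if bad:
        raise ValueError(f"unknown model ids {bad}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    s_sim, s_env, s_mcmc = ss.spawn(3)
    window = Window(*config.window)

    if config.simulate is not None:
        study = generate_study(
            seed=s_sim, window=window, **config.simulate
        )
        pattern, covariates = study.pattern, study.covariates
        record = study.diffusions[0]
        write_population(outdir / "population.csv", pattern, covariates)
        write_diffusion(outdir / "diffusion.csv", record)
    elif config.population is not None and config.diffusion is not None:
        pattern, covariates = read_population(
            config.population,
            window=window,
            covariate_normalisation=config.normalisation,
        )
        record = read_diffusion(config.diffusion, population_ids=pattern.ids)
    else:
        raise ValueError("config needs either 'simulate' or population+diffusion paths")

    # exploratory stage: pair correlation with CSR envelope
    r_max = config.r_grid_max or 0.49 * pattern.window.shorter_side
    r_grid = np.linspace(r_max / config.n_r, r_max, config.n_r)
    pcf = pair_correlation(pattern, r_grid)
    pcf.envelope_low, pcf.envelope_high = csr_envelope(
        pattern, r_grid, n_sim=config.n_envelope, seed=s_env
    )
    write_pcf(outdir / "pcf.csv", pcf)
    suggestion = suggest_interaction_radius(pcf)

    if config.radius == "auto":
        if suggestion.radius is None:
            raise ValueError(
                "pattern is consistent with CSR: no interaction radius can be "
                "suggested; set 'radius' explicitly"
            )
        radius = suggestion.radius
    else:
        radius = float(config.radius)
    (outdir / "radius.json").write_text(
        json.dumps(
            {
                "radius": radius,
                "suggested": suggestion.radius,
                "csr": suggestion.csr,
                "regular": suggestion.regular,
            },
            indent=2,
        )
    )

    pattern = pattern.with_radius(radius)
    A = association_matrix(pattern, normalisation=config.association_normalisation)
    write_association(outdir / "association.csv", A)

    trace = rjmcmc_sample(
        config.models,
        record,
        A,
        covariates,
        n_iter=config.n_iter,
        burn_in=config.burn_in,
        tuning=config.tuning,
        move_prob=config.move_prob,
        seed=s_mcmc,
    )
    trace_df = pd.DataFrame(
        {"iteration": np.arange(trace.n_iter), "model": trace.models}
        | {k: v for k, v in trace.params.items()}
    )
    trace_df.to_csv(outdir / "trace.csv", index=False)
    summary = posterior_summary(trace)
    pd.DataFrame(
        [
            {"parameter": k, "mean": m, "low": lo, "high": hi}
            for k, (m, lo, hi) in summary.params.items()
        ]
    ).to_csv(outdir / "summary.csv", index=False)

    models_sorted = sorted(config.models)
    retained = trace.retained_models()
    counts = {m: int((retained == m).sum()) for m in models_sorted}
    bayes = {
        f"{a}_vs_{b}": bayes_factor_from_counts(counts[a], counts[b])
        for a in models_sorted
        for b in models_sorted
        if a < b and counts[b] > 0
    }
    (outdir / "model_probs.json").write_text(
        json.dumps(
            {
                "counts": counts,
                "probabilities": {m: c / retained.size for m, c in counts.items()},
                "bayes_factors": bayes,
            },
            indent=2,
        )
    )

    results = {
        "outdir": str(outdir),
        "radius": radius,
        "model_probabilities": {m: c / retained.size for m, c in counts.items()},
        "bayes_factors": bayes,
        "summary": summary.params,
    }

    if config.run_wave and record.informative and record.n_events >= 5:
        wave = wave_of_advance(pattern, record)
        pd.DataFrame([wave.__dict__]).to_csv(outdir / "wave.csv", index=False)
        results["wave_r_squared"] = wave.r_squared

    manifest = {
        "package": "snbda",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "numpy": np.__version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return results
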