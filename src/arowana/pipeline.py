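"""End-to-end orchestration: simulate -> encode -> train -> select -> estimate.

``run_pipeline`` performs the full analysis from one :class:`RunConfig`
and returns an :class:`InferenceReport`; ``run_stats`` computes the
diversity/differentiation suite for a genotype file.  Two scale presets
are provided: ``paper`` mirrors the published protocol (50,000 training
simulations per scenario, 25 epochs, 10^6 parameter-estimation
simulations) and ``desk`` is a workstation-scale configuration used by
the test-suite and the reproduction scripts.
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

from . import __version__
from .encode import EncoderConfig, make_training_tensors, matrix_to_image
from .netinfer import (
    NetConfig,
    ParamNormalizer,
    estimate_params,
    evaluate_classifier,
    select_model,
    train_classifier,
    train_regressor,
)
from .popstats import GenotypeMatrix, diversity, pairwise_fst, summarize_dataset
from .simulate import (
    DatasetShape,
    PriorConfig,
    draw_priors,
    simulate_batch,
    simulate_dataset,
)
from .synthdata import SynthConfig, generate_pseudo_empirical

logger = logging.getLogger("arowana")

__all__ = ["RunConfig", "InferenceReport", "run_pipeline", "run_stats", "SCALE_PRESETS"]

SCALE_PRESETS = {
    # n_per_model, test_n per model, epochs, estimation sims (train+test)
    "paper": {"n_per_model": 50_000, "test_n": 500, "epochs": 25,
              "estimation_train_n": 1_000_000, "estimation_test_n": 2_000},
    "desk": {"n_per_model": 2_000, "test_n": 200, "epochs": 10,
             "estimation_train_n": 20_000, "estimation_test_n": 2_000},
}


@dataclass
class RunConfig:
    priors: PriorConfig = field(default_factory=PriorConfig)
    shape: DatasetShape = field(default_factory=lambda: DatasetShape(11, 2, 400))
    encoder: EncoderConfig = field(default_factory=lambda: EncoderConfig(rows_fixed=26, cols_fixed=400))
    net: NetConfig = field(default_factory=lambda: NetConfig(
        architecture="conv1d", conv_filters=(64, 64), dense_units=128,
        pool_sizes=((1, 4), (1, 2)), epochs=10))
    synth: SynthConfig = field(default_factory=SynthConfig)
    scale: str = "desk"
    n_per_model: int | None = None       # overrides the preset when set
    test_n: int | None = None
    estimation_train_n: int | None = None
    estimation_test_n: int | None = None
    n_bootstrap: int = 200
    seed: int = 0
    output_dir: str | None = None

    def resolved(self) -> dict:
        if self.scale not in SCALE_PRESETS:
            raise ValueError(f"unknown scale preset {self.scale!r}")
        preset = dict(SCALE_PRESETS[self.scale])
        for key in ("n_per_model", "test_n", "estimation_train_n", "estimation_test_n"):
            override = getattr(self, key)
            if override is not None:
                preset[key] = override
        return preset

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class InferenceReport:
    config: dict
    model_selection: dict
    selected_model: int
    empirical_posteriors: list[float]
    param_estimate: dict
    data_summary: dict
    diversity: dict | None
    fst: dict | None
    provenance: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.time()


def run_pipeline(config: RunConfig, empirical: GenotypeMatrix | None = None) -> InferenceReport:
    """Full analysis for one (possibly synthetic) genotype dataset.

    When ``empirical`` is None a pseudo-empirical dataset is simulated
    under scenario 3 at mid-prior parameter values and flagged in the
    report.  Stages: training-set simulation and encoding, classifier
    training and evaluation, model selection on the empirical tensor,
    parameter-estimation simulations under the selected model, regressor
    training and bootstrap parameter estimation, plus the diversity/F_ST
    summary of the input data.
    """
    scale = config.resolved()
    root_ss = np.random.SeedSequence(config.seed)
    seeds = root_ss.generate_state(8) % (2 ** 31)
    pseudo = empirical is None
    if pseudo:
        mid = _mid_prior_scenario(config.priors)
        empirical = generate_pseudo_empirical(
            mid, config.shape, missing_rate=config.synth.missing_rate,
            rng_seed=int(seeds[0]))

    # empirical genotypes are unphased diploids, so the whole pipeline runs
    # in diploid-collapsed encoding (simulated haplotypes paired the same
    # way) for train/serve consistency
    n_dip = config.shape.n_dip_deme1 + config.shape.n_dip_deme2
    encoder = dataclasses.replace(config.encoder, ploidy_mode="diploid-collapsed",
                                  rows_fixed=n_dip)

    t0 = _stage("simulate+encode training sets")
    batch = simulate_batch(config.priors, config.shape,
                           scale["n_per_model"] + scale["test_n"],
                           {1, 2, 3, 4}, rng_seed=int(seeds[1]))
    train, test = make_training_tensors(
        list(batch), encoder, scale["n_per_model"], scale["test_n"],
        rng_seed=int(seeds[2]))
    logger.info("training data ready in %.1fs", time.time() - t0)

    t0 = _stage("train classifier")
    net_cfg = dataclasses.replace(config.net, epochs=scale["epochs"],
                                  task="classify", rng_seed=int(seeds[3]))
    clf, _ = train_classifier(train, net_cfg)
    selection = evaluate_classifier(clf, test)
    logger.info("classifier trained in %.1fs (test acc %.3f)",
                time.time() - t0, selection.overall_test_accuracy)

    emp_matrix = empirical.as_float_matrix()
    emp_labels = np.asarray([0 if p.startswith("TAb") else 1 for p in empirical.populations])
    # the empirical matrix already has one diploid row per individual
    emp_encoder = dataclasses.replace(encoder, ploidy_mode="haploid")
    emp_tensor = matrix_to_image(emp_matrix, emp_encoder, deme_labels=emp_labels).values
    posteriors = select_model(clf, emp_tensor)
    selected = int(clf.class_ids[int(np.argmax(posteriors))])

    t0 = _stage(f"parameter-estimation simulations under model {selected}")
    est_model = selected if selected in (3, 4) else 3  # ratios defined for 3/4 only
    normalizer = ParamNormalizer(config.priors)
    Xe, Ye = _simulate_regression_set(
        config, encoder, est_model,
        scale["estimation_train_n"] + scale["estimation_test_n"],
        normalizer, rng_seed=int(seeds[4]))
    n_tr = scale["estimation_train_n"]
    # regression uses the site-order-invariant readout (see docs/methods.md)
    reg_cfg = dataclasses.replace(config.net, epochs=scale["epochs"],
                                  task="regress", pool_type="avg",
                                  readout="gap", dropout=0.15, conv_dropout=0.05,
                                  rng_seed=int(seeds[5]))
    regressor = train_regressor((Xe[:n_tr], Ye[:n_tr]), reg_cfg)
    from .netinfer import score_regression
    preds = regressor.predict(Xe[n_tr:])
    scores = score_regression(preds, Ye[n_tr:])
    logger.info("regressor done in %.1fs", time.time() - t0)

    estimate = estimate_params(
        regressor, emp_matrix, emp_labels, emp_encoder, normalizer,
        n_bootstrap=config.n_bootstrap, rng_seed=int(seeds[6]))
    estimate.rmse = {k: v[0] for k, v in scores.items()}
    estimate.spearman_rho = {k: v[1] for k, v in scores.items()}

    div = fst = None
    try:
        div = diversity(empirical).table.to_dict(orient="index")
        fst = pairwise_fst(empirical).values.to_dict(orient="index")
    except ValueError as exc:                     # e.g. single population
        logger.warning("popstats skipped: %s", exc)

    return InferenceReport(
        config=config.to_dict(),
        model_selection=selection.to_dict(),
        selected_model=selected,
        empirical_posteriors=[float(p) for p in posteriors],
        param_estimate=estimate.to_dict(),
        data_summary={**summarize_dataset(empirical), "pseudo_empirical": pseudo},
        diversity=div,
        fst=fst,
        provenance={
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "version": __version__,
            "numpy": np.__version__,
        },
    )


def _mid_prior_scenario(priors: PriorConfig):
    """Scenario-3 parameters at the midpoint of every prior range."""
    from .simulate import ScenarioParams, derived_quantities

    ne = float(np.mean(priors.ne_range))
    dt = float(np.mean(priors.dt_range))
    g = float(np.mean(priors.g_range))
    theta, ct = derived_quantities(priors, ne, dt, g)
    return ScenarioParams(
        model_id=3, ne=ne, dt=dt, g=g, theta=theta, ct=ct,
        founder_ratio=float(np.mean(priors.founder_ratio_range)),
        growth_ratio=float(np.mean(priors.growth_ratio_range)),
    )


def _simulate_regression_set(
    config: RunConfig, encoder: EncoderConfig, model_id: int, n: int,
    normalizer: ParamNormalizer, rng_seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Encoded tensors plus normalized (Ne, DT, founder, growth) targets."""
    children = np.random.SeedSequence(rng_seed).spawn(n)
    X = np.empty((n, encoder.rows_fixed, encoder.cols_fixed, 1),
                 dtype=np.float32)
    Y = np.empty((n, 4), dtype=np.float64)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        params = draw_priors(config.priors, model_id, rng)
        ds = simulate_dataset(params, config.shape, rng)
        X[i] = matrix_to_image(ds, encoder).values
        Y[i] = normalizer.normalize(
            [params.ne, params.dt, params.founder_ratio, params.growth_ratio])
    return X, Y


def run_stats(
    source: str | Path, format: str, popmap: str | Path | dict, n_axes: int = 2
) -> dict:
    """Diversity table, pairwise F_ST and PCoA for a genotype file."""
    from .popstats import pcoa, read_genotypes

    gm = read_genotypes(source, format, popmap)
    coords, eigvals = pcoa(gm, n_axes=n_axes)
    return {
        "summary": summarize_dataset(gm),
        "diversity": diversity(gm),
        "fst": pairwise_fst(gm),
        "pcoa_coordinates": coords,
        "pcoa_eigenvalues": eigvals,
    }
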