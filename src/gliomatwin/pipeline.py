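"""End-to-end experiment driver: generate -> calibrate -> predict.

This is the reproducibility layer tying the pipeline together as plain
Python functions (the package is library-first; the functions here and the
scripts in ``examples/`` are the interface).  A ``RunConfig`` fully
determines a run — every stochastic stage draws its seed from the one
top-level seed — and round-trips through JSON unchanged.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .laplace import LaplacePosterior, misfit_hessian_gevp
from .map_estimation import (
    MAPResult,
    NewtonCGSettings,
    TumorInverseProblem,
    solve_map,
)
from .patient import VirtualPatientData, VirtualPatientSpec, generate_observations
from .prior import BlockPrior, default_block_prior
from .qoi import PredictionSetup, compare_distributions, pushforward_qoi
from . import qoi as _qoi


@dataclass
class RunConfig:
    """Serializable description of one virtual-patient study."""

    seed: int = 0
    schedules: tuple = ("daily", "weekly", "fortnightly")
    n_samples: int = 500
    eig_rank: int = 50
    eig_oversampling: int = 10
    max_newton: int = 50
    grad_rtol: float = 1e-5
    predict_from: str = "last_observation"  # or "initial"
    spec_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "schedules" in d:
            d["schedules"] = tuple(d["schedules"])
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        return cls.from_dict(json.loads(s))


def run_generate(config: RunConfig, imaging: str) -> VirtualPatientData:
    """Synthesize one virtual patient under the given imaging schedule."""
    spec = VirtualPatientSpec(
        imaging=imaging, seed=config.seed, **config.spec_overrides
    )
    return data_with_recorded_seeds(generate_observations(spec), config)


def data_with_recorded_seeds(data: VirtualPatientData, config: RunConfig):
    data.manifest = {"seed": config.seed, "spec": _spec_dict(data.spec)}
    return data


def _spec_dict(spec: VirtualPatientSpec) -> dict:
    d = dataclasses.asdict(spec)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    return d


@dataclass
class CalibrationResult:
    problem: TumorInverseProblem
    map_result: MAPResult
    posterior: LaplacePosterior


def run_calibrate(
    data: VirtualPatientData, config: RunConfig, prior: BlockPrior | None = None
) -> CalibrationResult:
    """MAP estimation + low-rank Laplace posterior on the coarse mesh."""
    coarse = data.coarse_domain
    prior = prior or default_block_prior(coarse)
    problem = TumorInverseProblem(
        domain=coarse,
        prior=prior,
        obs=data.obs,
        u0=data.u0_coarse,
        schedule=data.schedule,
        settings=data.spec.forward_settings(),
    )
    nk = NewtonCGSettings(
        max_newton=config.max_newton, grad_rtol=config.grad_rtol
    )
    map_res = solve_map(problem, settings=nk)
    gevp_seed = int(np.random.SeedSequence([config.seed, 1]).generate_state(1)[0] % 2**31)
    pairs = misfit_hessian_gevp(
        problem, map_res.m_map,
        k=config.eig_rank, p=config.eig_oversampling, seed=gevp_seed,
    )
    post = LaplacePosterior(m_map=map_res.m_map, pairs=pairs, prior=prior)
    return CalibrationResult(problem=problem, map_result=map_res, posterior=post)


def prediction_setup(
    data: VirtualPatientData, predict_from: str = "last_observation"
) -> PredictionSetup:
    """Prediction scored on the coarse mesh against fine-mesh voxel truth.

    ``predict_from="last_observation"`` mimics clinical deployment: the
    initial state is reconstructed from the final imaging visit (nearest-
    voxel lookup, clamped to [0, 1]) and the simulation window is
    (t_f, t_pred).  ``"initial"`` instead simulates from the true t=0 seed
    through the whole history.
    """
    from .geometry import voxels_to_fem

    spec = data.spec
    u_true = data.u_pred_true
    if predict_from == "last_observation":
        u0 = np.clip(
            voxels_to_fem(data.obs.data[:, -1], data.grid, data.coarse_domain),
            0.0, 1.0,
        )
        # only measurable tumor is visible on imaging: sub-threshold voxel
        # values are noise speckle, which the logistic term would otherwise
        # amplify into spurious domain-wide growth over the horizon
        u0[u0 <= spec.threshold] = 0.0
        t0 = float(data.obs.times[-1])
    elif predict_from == "initial":
        u0, t0 = data.u0_coarse, 0.0
    else:
        raise ValueError("predict_from must be 'last_observation' or 'initial'")
    return PredictionSetup(
        domain=data.coarse_domain,
        u0=u0,
        t0=t0,
        t_pred=spec.t_pred,
        schedule=data.schedule,
        settings=spec.forward_settings(),
        grid=data.grid,
        truth_voxels=data.truth_pred_voxels,
        truth_volume=_qoi.tumor_volume(u_true, data.fine_domain, spec.threshold),
        truth_cellularity=_qoi.total_tumor_cellularity(
            u_true, data.fine_domain, spec.threshold
        ),
        threshold=spec.threshold,
    )


def run_predict(
    data: VirtualPatientData,
    calib: CalibrationResult,
    config: RunConfig,
) -> dict:
    """Prior and posterior pushforwards plus the comparison statistics."""
    setup = prediction_setup(data, config.predict_from)
    seeds = np.random.SeedSequence([config.seed, 2]).generate_state(2) % 2**31
    prior_df = pushforward_qoi(
        calib.problem.prior, config.n_samples, int(seeds[0]), setup,
        provenance="prior",
    )
    post_df = pushforward_qoi(
        calib.posterior, config.n_samples, int(seeds[1]), setup,
        provenance="laplace",
    )
    tests = {}
    for q in ("rel_error_volume", "ccc"):
        a = post_df.loc[~post_df.failed, q].to_numpy()
        b = prior_df.loc[~prior_df.failed, q].to_numpy()
        mw, lev = compare_distributions(a, b)
        tests[q] = {"mannwhitney_p": mw, "levene_p": lev}
    return {"prior": prior_df, "posterior": post_df, "tests": tests,
            "setup": setup}


def run_imaging_frequency_study(config: RunConfig) -> dict:
    """The full frequency study: calibrate and predict per schedule.

    Returns per-schedule results (MAP summary, GEVP spectrum, pushforward
    frames, test p-values); the data differ only in imaging days — domain,
    truth and noise realization pattern are regenerated per schedule from the
    same top-level seed so the eigenvalue comparison is matched.
    """
    out = {}
    for imaging in config.schedules:
        data = run_generate(config, imaging)
        calib = run_calibrate(data, config)
        pred = run_predict(data, calib, config)
        out[imaging] = {
            "data": data,
            "calibration": calib,
            "eigenvalues": calib.posterior.pairs.eigenvalues,
            "prediction": pred,
        }
    return out


def qoi_table(results: dict) -> pd.DataFrame:
    """Tidy per-sample QoI table across schedules and provenances."""
    frames = []
    for imaging, r in results.items():
        for key in ("prior", "posterior"):
            df = r["prediction"][key].copy()
            df["imaging"] = imaging
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
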