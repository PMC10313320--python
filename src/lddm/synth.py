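"""Synthetic datasets with known ground truth.

Two table kinds are generated, matching the schemas the fitting modules
read: trial-level RT/choice data simulated from a known parameterization of
one of the circuit models, and condition-mean firing-rate tables whose
means follow the divisive-normalization equilibrium with additive Gaussian
measurement noise.  Each generator writes (or returns) the dataset together
with a ground-truth record sufficient to rerun it bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .behavior import CANONICAL_COHERENCES, RTDataset, simulate_rt_distribution
from .params import ModelParams
from .rates import NormalizationDataset, default_design, equilibrium_rates

__all__ = [
    "GeneratorSpec",
    "generate_rt_dataset",
    "generate_rates_dataset",
    "DEFAULT_RT_TRUTH",
    "DEFAULT_RATES_TRUTH",
]

#: WTA-regime generating truth for recovery experiments: all parameters
#: nonzero (so relative recovery error is well defined) and time constants
#: fast enough for realistic sub-1.3-s mean reaction times
DEFAULT_RT_TRUTH = dict(
    alpha=8.0, beta=1.35, sigma=20.0, S=1500.0,
    tau_R=0.08, tau_G=0.12, tau_D=0.15,
)

#: generating truth for firing-rate tables; B_R and the combined
#: B_G - alpha term take the published fit values, Rmax sets a realistic
#: 0-60 Hz response range
DEFAULT_RATES_TRUTH = dict(B_R=71.53, bg_minus_alpha=3.82, Rmax=30.0)


@dataclass
class GeneratorSpec:
    """What to generate: model, parameters, design and noise."""

    kind: str = "rt"  # "rt" | "rates"
    model: str = "lddm"
    params: dict = field(default_factory=dict)
    coherences: tuple = CANONICAL_COHERENCES
    trials_per_coherence: int = 600
    noise_sd_hz: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("rt", "rates"):
            raise ValueError("kind must be 'rt' or 'rates'")
        if self.trials_per_coherence < 1:
            raise ValueError("trials per coherence must be >= 1")


def generate_rt_dataset(
    spec: GeneratorSpec | None = None,
    csv_path=None,
    truth_path=None,
    max_censored_fraction: float = 0.2,
    **kwargs,
) -> tuple[RTDataset, dict]:
    """Simulate a trial-level RT dataset from known LDDM parameters.

    Returns the dataset and a truth record (parameters, design, seed,
    censored count).  Parameter sets that produce no decisions — e.g.
    a silent disinhibition gate, which never leaves the normalization
    regime — raise with the censored fraction in the message.
    """
    spec = spec or GeneratorSpec(kind="rt", **kwargs)
    vals = dict(DEFAULT_RT_TRUTH)
    vals.update(spec.params)
    params = ModelParams(B_R=0.0, B_G=0.0, **vals)
    pred = simulate_rt_distribution(
        params, spec.coherences, n_reps=spec.trials_per_coherence,
        seed=spec.seed, model=spec.model,
    )
    n_total = spec.trials_per_coherence * len(spec.coherences)
    n_cens = sum(c["n_censored"] for c in pred.values())
    if n_total - n_cens == 0 or n_cens / n_total > max_censored_fraction:
        raise ValueError(
            f"degenerate parameters: {n_cens}/{n_total} trials censored "
            f"({100.0 * n_cens / n_total:.1f}%)"
        )
    rows = []
    for coh in spec.coherences:
        cell = pred[float(coh)]
        for corr, key in ((True, "rt_correct"), (False, "rt_error")):
            for rt in cell[key]:
                choice = (0 if corr else 1) if coh > 0 else -1
                rows.append(
                    {"coherence": float(coh), "choice": choice,
                     "correct": bool(corr), "rt_s": float(rt)}
                )
    df = pd.DataFrame(rows).sort_values(["coherence", "rt_s"], kind="stable")
    df.insert(0, "trial_id", np.arange(len(df)))
    data = RTDataset(df.reset_index(drop=True))
    truth = {
        "kind": "rt", "model": spec.model, "params": vals,
        "coherences": [float(c) for c in spec.coherences],
        "trials_per_coherence": spec.trials_per_coherence,
        "seed": spec.seed, "n_censored": n_cens,
    }
    if csv_path is not None:
        data.to_csv(csv_path)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=1)
    return data, truth


def generate_rates_dataset(
    spec: GeneratorSpec | None = None,
    conditions: pd.DataFrame | None = None,
    csv_path=None,
    truth_path=None,
    **kwargs,
) -> tuple[NormalizationDataset, dict]:
    """Condition-mean firing rates with divisive-normalization structure.

    Means follow the LDDM equilibrium at the generating truth; i.i.d.
    Gaussian noise (``noise_sd_hz``) is added per condition and negative
    draws are clamped at zero (count recorded in the truth record).
    """
    spec = spec or GeneratorSpec(kind="rates", **kwargs)
    vals = dict(DEFAULT_RATES_TRUTH)
    vals.update(spec.params)
    design = conditions if conditions is not None else default_design()
    rng = np.random.default_rng(spec.seed)
    means = np.array(
        [
            equilibrium_rates("lddm", vals, (r.V1_ul, r.V2_ul, r.V3_ul))
            for r in design.itertuples()
        ]
    )
    noisy = means + spec.noise_sd_hz * rng.standard_normal(len(means))
    n_clamped = int((noisy < 0).sum())
    noisy = np.maximum(noisy, 0.0)
    table = design.copy()
    table["rate_hz"] = noisy
    data = NormalizationDataset(table)
    truth = {
        "kind": "rates", "model": "lddm", "params": vals,
        "noise_sd_hz": spec.noise_sd_hz, "seed": spec.seed,
        "n_clamped": n_clamped,
        "conditions": design.to_dict(orient="list"),
    }
    if csv_path is not None:
        with open(csv_path, "w") as fh:
            fh.write("# synthetic trinary-design firing rates; conditions "
                     "listed row-wise below\n")
            data.table.to_csv(fh, index=False)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=1)
    return data, truth
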