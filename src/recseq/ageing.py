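"""Stochastic per-division model of eccDNA copy number in an ageing mother cell.

Each division applies, in order:

1. **formation** — ``Poisson(lambda_form)`` new circles arise de novo
   (transcription-driven excision from the chromosomal locus);
2. **replication** — every circle duplicates independently with probability
   ``p_rep`` (the efficiency of the circle's replication origin);
3. **segregation** — every resulting copy is retained in the mother
   independently with probability ``p_ret`` (asymmetric retention via
   nuclear-pore tethering; copies lost to the daughter are gone, because
   daughters are non-replicative in the mother-enrichment system and are not
   tracked).

Writing ``a = (1 + p_rep) * p_ret``, the copy-number expectation after ``t``
divisions is exactly

    E[c_t] = a^t * c0 + lambda_form * a * (a^t - 1) / (a - 1)

(``c0 + lambda_form * t`` when ``a == 1``). ``a < 1`` is the regime where a
circle species cannot maintain itself without fresh formation — loss to
daughters outpaces replication — while ``a > 1`` gives exponential
amplification, the classic rDNA-circle regime and the behaviour restored by
adding an efficient replication origin to a circle.

The named presets encode qualitative contrasts (induced vs uninduced locus,
retention mutants, origin-rescued circles); their magnitudes are free
parameters of the simulator, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError


@dataclass(frozen=True)
class DynamicsParams:
    """Per-division dynamics of one circle species in one condition.

    lambda_form : expected de novo circles formed per division (>= 0)
    p_rep       : per-circle per-division duplication probability in [0, 1]
    p_ret       : per-copy probability of retention in the mother in [0, 1]
    c0          : initial copy number (integer >= 0)
    n_divisions : trajectory length
    seed        : RNG seed for ``simulate_mother``
    """

    lambda_form: float = 0.0
    p_rep: float = 0.0
    p_ret: float = 1.0
    c0: int = 0
    n_divisions: int = 24
    seed: int = 0

    def __post_init__(self):
        if self.lambda_form < 0:
            raise InputError("lambda_form must be >= 0")
        for name in ("p_rep", "p_ret"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {v}")
        if self.c0 < 0 or int(self.c0) != self.c0:
            raise InputError("c0 must be a non-negative integer")
        if self.n_divisions < 0:
            raise InputError("n_divisions must be >= 0")

    @property
    def a(self) -> float:
        """Per-division multiplicative factor (1 + p_rep) * p_ret."""
        return (1.0 + self.p_rep) * self.p_ret


@dataclass(frozen=True)
class Trajectory:
    """Copy numbers indexed by division 0..n_divisions."""

    copies: np.ndarray

    def __post_init__(self):
        if np.any(np.asarray(self.copies) < 0):
            raise InputError("negative copy number in trajectory")


def simulate_mothers(
    params: DynamicsParams, n_mothers: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Simulate ``n_mothers`` independent mothers; returns (n_mothers, t+1) ints."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    t = params.n_divisions
    out = np.empty((n_mothers, t + 1), dtype=np.int64)
    c = np.full(n_mothers, int(params.c0), dtype=np.int64)
    out[:, 0] = c
    for d in range(1, t + 1):
        if params.lambda_form > 0:
            c = c + rng.poisson(params.lambda_form, size=n_mothers)
        dup = rng.binomial(c, params.p_rep) if params.p_rep > 0 else 0
        total = c + dup
        c = rng.binomial(total, params.p_ret) if params.p_ret < 1 else total
        out[:, d] = c
    return out


def simulate_mother(params: DynamicsParams) -> Trajectory:
    """One mother-cell trajectory, reproducible under a fixed seed."""
    return Trajectory(simulate_mothers(params, 1)[0])


def expected_copies(params: DynamicsParams, t: int) -> float:
    """Exact expectation of the process after ``t`` divisions."""
    if t > params.n_divisions:
        raise InputError("t exceeds n_divisions")
    a = params.a
    if abs(a - 1.0) < 1e-12:
        return params.c0 + params.lambda_form * t
    return (a**t) * params.c0 + params.lambda_form * a * (a**t - 1.0) / (a - 1.0)


# ---------------------------------------------------------------------------
# Presets
#
# Magnitudes are illustrative constants chosen so the qualitative contrasts
# hold (see docs/methods.md): induced formation 10x the basal rate; the
# native array circle has a < 1 (lost without formation) while the
# origin-rescued and rDNA-like circles have a > 1 (amplified); the retention
# mutant halves p_ret. They are NOT experimental measurements.

PRESETS: dict[str, dict] = {
    "cup1_wt_plus_cu": dict(lambda_form=0.5, p_rep=0.05, p_ret=0.8, c0=0),
    "cup1_wt_minus_cu": dict(lambda_form=0.05, p_rep=0.05, p_ret=0.8, c0=0),
    "cup1_spt3_plus_cu": dict(lambda_form=0.5, p_rep=0.05, p_ret=0.5, c0=0),
    "cup1_sae2_plus_cu": dict(lambda_form=0.05, p_rep=0.05, p_ret=0.8, c0=0),
    "erc_wt": dict(lambda_form=0.05, p_rep=0.9, p_ret=0.8, c0=0),
    "subtelomere_wt": dict(lambda_form=0.1, p_rep=0.35, p_ret=0.8, c0=0),
    "ty_wt": dict(lambda_form=0.1, p_rep=0.35, p_ret=0.8, c0=0),
    "marked_circle": dict(lambda_form=0.0, p_rep=0.05, p_ret=0.8, c0=20),
    "ars_cup1": dict(lambda_form=0.0, p_rep=0.95, p_ret=0.8, c0=20),
}


def preset_params(name: str, n_divisions: int = 24, seed: int = 0) -> DynamicsParams:
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; known: {sorted(PRESETS)}")
    return DynamicsParams(n_divisions=n_divisions, seed=seed, **PRESETS[name])


def simulate_cohort(
    params_by_key: Mapping[tuple[str, str], DynamicsParams | str],
    n_mothers: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Aggregate independent mothers per (locus, condition).

    Values may be :class:`DynamicsParams` or preset names. Returns a tidy
    frame with columns locus, condition, division, mean_copies, sd.
    """
    if n_mothers < 1:
        raise InputError("n_mothers must be >= 1")
    rows = []
    for i, ((locus, condition), p) in enumerate(sorted(params_by_key.items())):
        if isinstance(p, str):
            p = preset_params(p)
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        traj = simulate_mothers(p, n_mothers, rng)
        mean = traj.mean(axis=0)
        sd = traj.std(axis=0, ddof=1) if n_mothers > 1 else np.zeros(traj.shape[1])
        for d in range(traj.shape[1]):
            rows.append((locus, condition, d, mean[d], sd[d]))
    return pd.DataFrame(
        rows, columns=["locus", "condition", "division", "mean_copies", "sd"]
    )


def write_cohort_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
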