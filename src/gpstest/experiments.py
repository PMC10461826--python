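"""Type-1-error and power experiments over scenario grids.

Each experiment runs ``n_reps`` replicate pairs per scenario, applies the
requested tests and reports the rejection proportion at ``alpha`` with a
Wilson 95% score interval, mirroring how simulation studies of GWAS
independence tests are conventionally summarised.
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import InputValidationError
from .hoeffding import hoeffding_test
from .inference import gps_gev_test
from .simulate import SimSpec, simulate_pair, with_seed

METHODS = ("gps-gev", "gps-exp", "hoeffding")

_SCENARIO_COLS = (
    "n_snps", "pi1_a", "pi1_b", "n_shared", "zmean", "zsd",
    "rho", "block_size", "block_r",
)


def wilson_ci(successes: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson 95% (by default) score interval for a proportion."""
    lo, hi = proportion_confint(successes, n, alpha=1 - conf, method="wilson")
    return float(lo), float(hi)


def _run_grid(
    specs: Iterable[SimSpec],
    n_reps: int,
    alpha: float,
    seed: int,
    methods: Sequence[str],
    n_perm: int,
    backend: str,
    hoeffding_n_perm: int,
) -> pd.DataFrame:
    if not 0.0 <= alpha <= 1.0:
        raise InputValidationError(f"alpha must be in [0, 1], got {alpha}")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise InputValidationError(f"unknown method(s): {sorted(unknown)}")
    want_gps = "gps-gev" in methods or "gps-exp" in methods
    master = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for spec in specs:
        rejections = {m: 0 for m in methods}
        # independent seed pools per scenario, below 2^31 for portability
        seeds = master.integers(0, 2**31 - 1, size=(n_reps, 2))
        for rep in range(n_reps):
            pair = simulate_pair(with_seed(spec, int(seeds[rep, 0])))
            if want_gps:
                rep_gev = gps_gev_test(
                    pair, n_perm=n_perm, seed=int(seeds[rep, 1]),
                    backend=backend,
                )
                if "gps-gev" in methods and rep_gev.p_value <= alpha:
                    rejections["gps-gev"] += 1
                if "gps-exp" in methods and rep_gev.p_value_exp <= alpha:
                    rejections["gps-exp"] += 1
            if "hoeffding" in methods:
                rep_h = hoeffding_test(
                    pair, n_perm=hoeffding_n_perm, seed=int(seeds[rep, 1])
                )
                if rep_h.p_value <= alpha:
                    rejections["hoeffding"] += 1
        scenario = {k: v for k, v in asdict(spec).items() if k != "seed"}
        for m in methods:
            lo, hi = wilson_ci(rejections[m], n_reps)
            rows.append({
                **scenario,
                "method": m,
                "rejection_rate": rejections[m] / n_reps,
                "wilson_lo": lo,
                "wilson_hi": hi,
                "n_reps": n_reps,
            })
    return pd.DataFrame(rows)


def run_type1_experiment(
    specs: Iterable[SimSpec],
    n_reps: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    methods: Sequence[str] = ("gps-gev", "gps-exp"),
    n_perm: int = 1000,
    backend: str = "tree",
    hoeffding_n_perm: int = 400,
) -> pd.DataFrame:
    """Rejection proportions under null scenarios (no shared signal)."""
    specs = list(specs)
    for s in specs:
        if s.n_shared != 0:
            raise InputValidationError(
                "type-1 scenarios must have n_shared == 0"
            )
    return _run_grid(specs, n_reps, alpha, seed, methods, n_perm,
                     backend, hoeffding_n_perm)


def run_power_experiment(
    specs: Iterable[SimSpec],
    n_reps: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    methods: Sequence[str] = ("gps-gev", "gps-exp"),
    n_perm: int = 1000,
    backend: str = "tree",
    hoeffding_n_perm: int = 400,
) -> pd.DataFrame:
    """Rejection proportions under shared-effect scenarios."""
    return _run_grid(list(specs), n_reps, alpha, seed, methods, n_perm,
                     backend, hoeffding_n_perm)


def read_scenario_grid(path) -> list[SimSpec]:
    """Read a scenario grid from a TSV config (columns = SimSpec fields)."""
    df = pd.read_csv(path, sep="\t")
    if "n_snps" not in df.columns:
        raise InputValidationError("scenario config needs an n_snps column")
    extra = set(df.columns) - set(_SCENARIO_COLS)
    if extra:
        raise InputValidationError(
            f"unknown scenario column(s): {sorted(extra)}"
        )
    specs = []
    for row in df.to_dict("records"):
        kwargs = {k: v for k, v in row.items() if not pd.isna(v)}
        if "block_size" in kwargs:
            kwargs["block_size"] = int(kwargs["block_size"])
        for k in ("n_snps", "n_shared"):
            if k in kwargs:
                kwargs[k] = int(kwargs[k])
        specs.append(SimSpec(**kwargs))
    return specs
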