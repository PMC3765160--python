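"""Synthetic-data engine: arm-in-cage bioassay simulator and congeneric series.

Two generators live here.

**Staircase bioassay simulator.**  The assay it emulates: a cloth patch
treated at some surface dosage is presented for one minute to a cage of
roughly 500 host-seeking female *Aedes aegypti*; five or more bites
(~1% of the cage) fail the patch, 0–4 bites pass it.  Testing starts at
the median dose of a ladder and steps down after a pass, up after a
fail, stopping once a pass and a fail occur at adjacent doses; the MED
estimate is the lowest passing dose.  Because the failure threshold is
~1% of the insects, the MED estimates the dose with 99% repellency
(ED99).  The per-mosquito bite probability follows a log-logistic
dose-response ``p(d) = p0 / (1 + (d/ed50)^hill)`` — the protocol defines
no functional form, so the shape is exposed in the parameters and can be
swapped.  The cage size is jittered ±10% per test, as in the protocol.

**Congeneric series generator.**  Produces an amide series (one scaffold,
two variable substituents) whose true log-activity is a linear function
of chosen local atomic field values at the substituted positions plus
Gaussian noise — a synthetic stand-in for the published training series
with a known structure-activity signal, used for recovery tests of the
QSAR pipeline.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .atomic_fields import compute_fields
from .molgraph import parse_smiles

__all__ = [
    "BioassayParams",
    "StaircaseResult",
    "default_dose_ladder",
    "bite_count",
    "analytic_med",
    "staircase",
    "run_assay",
    "EffectSpec",
    "CongenericSeries",
    "generate_congeneric_series",
    "DEFAULT_R1_POOL",
    "DEFAULT_R2_POOL",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BioassayParams:
    """Stochastic assay parameters.

    ``n_mosquitoes`` is the nominal cage population (jittered uniformly by
    ``count_jitter`` per test); ``p0`` the per-mosquito probability of
    biting an untreated patch within the 1-minute exposure; ``ed50`` and
    ``hill`` the dose-response location/slope; ``fail_threshold`` the bite
    count at which a patch fails (5 bites of ~500 insects ≈ the 1%
    criterion); ``subject_jitter_sd`` a lognormal spread of p0 between
    subjects; ``control_valid_p`` the probability a subject's control
    checks pass (invalid replicates are discarded, as in the protocol).
    """

    n_mosquitoes: int = 500
    count_jitter: float = 0.10
    p0: float = 0.8
    ed50: float = 0.01  # dose units (e.g. µmol/cm²)
    hill: float = 1.5
    fail_threshold: int = 5
    subject_count: int = 5
    subject_jitter_sd: float = 0.1
    control_valid_p: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.p0 <= 1:
            raise ValueError("p0 must be in (0, 1]")
        if self.ed50 <= 0 or self.hill <= 0:
            raise ValueError("ed50 and hill must be positive")
        if self.fail_threshold < 1:
            raise ValueError("fail_threshold must be >= 1")


def default_dose_ladder(
    lo: float = 0.0025, hi: float = 2.5, factor: float = 2.0
) -> List[float]:
    """Geometric dose ladder (2-fold spacing by default), ascending."""
    doses = [lo]
    while doses[-1] * factor <= hi * 1.0000001:
        doses.append(doses[-1] * factor)
    return doses


def _bite_probability(dose: float, params: BioassayParams, p0: float = None) -> float:
    p = params.p0 if p0 is None else p0
    if dose == 0:
        return p
    # evaluate the log-logistic in log space so extreme slopes cannot overflow
    log_term = params.hill * math.log(dose / params.ed50)
    if log_term > 700:
        return 0.0
    if log_term < -700:
        return p
    return p / (1.0 + math.exp(log_term))


def bite_count(
    dose: float, params: BioassayParams, rng: np.random.Generator,
    p0: Optional[float] = None,
) -> int:
    """Bites received in one 1-minute test at ``dose``.

    The cage population is drawn uniformly within ±``count_jitter`` of
    nominal and each mosquito bites independently with the dose-response
    probability.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    jitter = int(round(params.n_mosquitoes * params.count_jitter))
    n = int(rng.integers(params.n_mosquitoes - jitter, params.n_mosquitoes + jitter + 1))
    return int(rng.binomial(n, _bite_probability(dose, params, p0)))


def analytic_med(params: BioassayParams) -> float:
    """Dose at which the expected bite fraction equals the failure fraction.

    Solves ``p(d) = fail_threshold / n_mosquitoes`` for ``d`` — with the
    default 5-of-500 threshold this is the 1%-bite (ED99) dose:
    ``ed50 * (p0 * n / threshold - 1)^(1/hill)``.
    """
    p_fail = params.fail_threshold / params.n_mosquitoes
    if params.p0 <= p_fail:
        return 0.0  # even an untreated patch passes on average
    return params.ed50 * (params.p0 / p_fail - 1.0) ** (1.0 / params.hill)


@dataclass
class SubjectOutcome:
    med: Optional[float]  # None when censored above the ladder
    censored_high: bool
    at_floor: bool  # all doses passed; MED reported as <= min(ladder)


def staircase(
    params: BioassayParams,
    dose_ladder: Sequence[float],
    rng: np.random.Generator,
    p0: Optional[float] = None,
) -> SubjectOutcome:
    """One subject's staircase titration on ``dose_ladder``.

    Starts at the median ladder dose, steps down after a pass and up
    after a fail, and terminates once a pass and a fail have occurred at
    adjacent ladder doses; the MED is the lowest passing dose.  If every
    tested dose fails the result is censored above the ladder; if every
    dose passes the lowest ladder dose is flagged as an upper bound.
    """
    ladder = list(dose_ladder)
    if not ladder:
        raise ValueError("dose ladder is empty")
    if len(ladder) < 2:
        raise ValueError("dose ladder needs at least 2 doses")
    if any(b <= a for a, b in zip(ladder, ladder[1:])):
        raise ValueError("dose ladder must be strictly increasing")
    outcomes: Dict[int, bool] = {}  # ladder index -> passed
    i = (len(ladder) - 1) // 2
    while True:
        passed = bite_count(ladder[i], params, rng, p0) < params.fail_threshold
        outcomes[i] = passed
        if passed and i - 1 in outcomes and not outcomes[i - 1]:
            return SubjectOutcome(med=ladder[i], censored_high=False, at_floor=False)
        if not passed and i + 1 in outcomes and outcomes[i + 1]:
            return SubjectOutcome(med=ladder[i + 1], censored_high=False,
                                  at_floor=False)
        if passed:
            if i == 0:
                return SubjectOutcome(med=ladder[0], censored_high=False,
                                      at_floor=True)
            i -= 1
        else:
            if i == len(ladder) - 1:
                return SubjectOutcome(med=None, censored_high=True, at_floor=False)
            i += 1


@dataclass
class StaircaseResult:
    """Aggregated assay outcome: per-subject MEDs and their mean ± SE."""

    subject_meds: List[Optional[float]]
    mean_med: Optional[float]
    se_med: Optional[float]
    n_censored: int
    censored: bool  # all subjects censored


def run_assay(
    params: BioassayParams, dose_ladder: Optional[Sequence[float]] = None
) -> StaircaseResult:
    """Replicate the staircase over subjects and average the MEDs.

    Each subject's baseline bite probability is jittered lognormally
    (between-arm attractiveness differences); subjects whose control
    checks fail are redrawn.  The mean and standard error cover
    non-censored subjects only; with a single subject the SE is absent.
    Seeded and fully reproducible via ``params.seed``.
    """
    if params.subject_count < 1:
        raise ValueError("subject_count must be >= 1")
    ladder = list(dose_ladder) if dose_ladder is not None else default_dose_ladder()
    rng = np.random.default_rng(params.seed)
    meds: List[Optional[float]] = []
    done = 0
    while done < params.subject_count:
        if rng.random() > params.control_valid_p:
            continue  # replicate discarded by the control-patch gate
        p0 = min(1.0, params.p0 * float(rng.lognormal(0.0, params.subject_jitter_sd)))
        out = staircase(params, ladder, rng, p0)
        meds.append(out.med)
        done += 1
    finite = [m for m in meds if m is not None]
    n_cens = len(meds) - len(finite)
    if not finite:
        return StaircaseResult(meds, None, None, n_cens, censored=True)
    mean = float(np.mean(finite))
    se = (
        float(np.std(finite, ddof=1) / math.sqrt(len(finite)))
        if len(finite) > 1
        else None
    )
    return StaircaseResult(meds, mean, se, n_cens, censored=False)


# ---------------------------------------------------------------------------
# Congeneric series with known structure-activity signal
# ---------------------------------------------------------------------------

#: Substituent fragments; the first atom of each fragment is the attachment.
DEFAULT_R1_POOL = (
    "C", "CC", "CCC", "CCCC", "CCCCC", "C(C)C", "C(C)(C)C",
    "CCO", "CCCO", "CC=C", "C1CCCCC1", "c1ccccc1",
)
DEFAULT_R2_POOL = (
    "C", "CC", "CCC", "CCCC", "C(C)C", "CCO", "CC=C",
    "CCOC", "C1CCCCC1", "c1ccccc1",
)

#: Default true signal: substituent lipophilicity at both variable positions
#: drives the activity, with a weaker electrostatic term on the N side.
DEFAULT_EFFECT_SPEC: Dict[Tuple[str, str], float] = {
    ("R1", "Lipo"): 1.5,
    ("R2", "Lipo"): -1.0,
    ("R2", "Q"): 10.0,
}

EffectSpec = Dict[Tuple[str, str], float]


@dataclass
class CongenericSeries:
    """A generated series: SMILES, ids, true log MEDs and bookkeeping."""

    ids: List[str]
    smiles: List[str]
    log_med: np.ndarray  # noisy observed values
    log_med_true: np.ndarray  # noiseless linear part
    effect_spec: EffectSpec
    position_atoms: Dict[str, List[int]]  # position name -> atom index per compound
    intercept: float
    noise_sd: float
    seed: int


def generate_congeneric_series(
    n: int = 60,
    scaffold: str = "O=C({R1})N({R2})CC",
    r1_pool: Sequence[str] = DEFAULT_R1_POOL,
    r2_pool: Sequence[str] = DEFAULT_R2_POOL,
    effect_spec: Optional[EffectSpec] = None,
    noise_sd: float = 0.1,
    intercept: float = -0.5,
    seed: int = 0,
) -> CongenericSeries:
    """Enumerate an amide series with a declared linear field signal.

    The scaffold is an N-ethyl amide with a variable acyl substituent R1
    and N-substituent R2 drawn from the pools (attachment atom written
    first in each fragment).  For each compound the true log MED is::

        intercept + sum_w  w[(pos, field)] * field_value(attachment atom)

    plus ``Normal(0, noise_sd)`` noise.  Deterministic given ``seed``.

    Raises
    ------
    ValueError
        If the pools cannot produce ``n`` distinct molecules.
    """
    if n < 10:
        raise ValueError("n must be >= 10 for a meaningful series")
    effect_spec = dict(effect_spec) if effect_spec is not None else dict(
        DEFAULT_EFFECT_SPEC
    )
    combos = list(itertools.product(range(len(r1_pool)), range(len(r2_pool))))
    if n > len(combos):
        raise ValueError(
            f"substituent pools yield only {len(combos)} distinct molecules, "
            f"{n} requested"
        )
    rng = np.random.default_rng(seed)
    chosen = [combos[i] for i in rng.permutation(len(combos))[:n]]
    ids, smis, truths = [], [], []
    pos_atoms = {"R1": [], "R2": []}
    fields_needed = tuple(sorted({f for (_, f) in effect_spec}))
    for idx, (i1, i2) in enumerate(chosen):
        r1, r2 = r1_pool[i1], r2_pool[i2]
        smi = scaffold.format(R1=r1, R2=r2)
        cid = f"S{idx:03d}"
        g = parse_smiles(smi, cid)
        # atom order: O=0, C(carbonyl)=1, R1 atoms, N, R2 atoms, ethyl
        n_r1 = parse_smiles(r1, "_r1").n_atoms
        a_r1 = 2
        a_r2 = 3 + n_r1
        fv = compute_fields(g, fields=fields_needed or ("Lipo",))
        truth = intercept
        for (pos, fld), w in effect_spec.items():
            a = a_r1 if pos == "R1" else a_r2
            truth += w * fv.at(fld, a)
        ids.append(cid)
        smis.append(smi)
        truths.append(truth)
        pos_atoms["R1"].append(a_r1)
        pos_atoms["R2"].append(a_r2)
    truths = np.array(truths)
    noisy = truths + rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else truths.copy()
    return CongenericSeries(
        ids=ids,
        smiles=smis,
        log_med=noisy,
        log_med_true=truths,
        effect_spec=effect_spec,
        position_atoms=pos_atoms,
        intercept=intercept,
        noise_sd=noise_sd,
        seed=seed,
    )
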