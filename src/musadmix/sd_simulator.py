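"""Forward Wright–Fisher simulation of sex-chromosome drive introgression.

Models the introgression of "long" (high-copy, musculus-type Sly/Slx-like)
segregation-distorter haplotypes on the X and Y chromosomes from a donor
population into a recipient population of constant diploid size N, under:

* one-way migration: Poisson(Nm) donor migrants per generation, each
  carrying long-Y (males), long-X, donor mitochondria and donor ancestry 1,
  replacing random residents so N stays fixed;
* male-germline segregation distortion: a father with a long Y and a short
  X sires males and females at ratio (1+d):1, i.e. P(male) = (1+d)/(2+d);
  a long X fully restores the 1:1 ratio (Slx counteracts Sly);
* optional hybrid incompatibilities: viability-equivalent weights
  w = (1 - s_xhi * h_X)(1 - s_mito * h_M) where h_X is the mean mismatch
  between an individual's X-haplotype origins and its autosomal donor
  ancestry, and h_M the mitochondria/autosome mismatch.

Autosomal ancestry is an infinitesimal (blending) fraction: offspring
ancestry is the parental mean.  SD haplotypes are binary classes; the
copy-number biology is summarized by the single distortion parameter d.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd


class ExtinctionError(RuntimeError):
    """One sex went extinct; the replicate cannot continue."""


@dataclasses.dataclass
class SDParams:
    """Parameters of the drive-introgression model.

    n : recipient diploid population size
    nm : expected donor migrants per generation (N * m)
    d : fractional increase of the male:female birth ratio for distorting
        fathers (long-Y, short-X); 0.1-0.2 is the biologically stated range
    s_xhi : X-autosome hybrid-incompatibility selection coefficient
    s_mito : mitochondria-autosome incompatibility coefficient
    """

    n: int = 1000
    nm: float = 1.0
    d: float = 0.2
    s_xhi: float = 0.0
    s_mito: float = 0.0
    max_generations: int = 500
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("N must be >= 2")
        if self.nm < 0:
            raise ValueError("Nm must be >= 0")
        if self.d < 0:
            raise ValueError("d must be >= 0")
        for s in (self.s_xhi, self.s_mito):
            if not 0.0 <= s < 1.0:
                raise ValueError("selection coefficients must be in [0, 1)")
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")


@dataclasses.dataclass
class SDPopulationState:
    """Vectorized population state.

    Males carry one X (x1) and one Y; females carry two X copies (x1, x2).
    Haplotype arrays are 1 for the long (donor) class, 0 for short.
    """

    male: np.ndarray  # bool
    y_long: np.ndarray  # bool, meaningful for males
    x1_long: np.ndarray  # bool
    x2_long: np.ndarray  # bool, meaningful for females
    ancestry: np.ndarray  # float in [0, 1], donor fraction
    mito_donor: np.ndarray  # bool

    @property
    def n(self) -> int:
        return self.male.size

    def freq_long_y(self) -> float:
        males = self.male
        if not males.any():
            return float("nan")
        return float(self.y_long[males].mean())

    def freq_long_x(self) -> float:
        """Frequency of the long class among all X copies."""
        males = self.male
        n_x = males.sum() + 2 * (~males).sum()
        count = self.x1_long[males].sum() + (
            self.x1_long[~males].sum() + self.x2_long[~males].sum()
        )
        return float(count / n_x)

    def mean_ancestry(self) -> float:
        return float(self.ancestry.mean())

    def freq_donor_mito(self) -> float:
        return float(self.mito_donor.mean())


def initialize_population(
    params: SDParams,
    rng: np.random.Generator | None = None,
    introduce_long_y: int = 0,
) -> SDPopulationState:
    """All-recipient starting population.

    Sexes are Bernoulli(1/2); everyone carries short haplotypes, recipient
    mitochondria and ancestry 0.  ``introduce_long_y`` flips the Y class of
    that many random males (ancestry untouched), for single-introduction
    neutral-fixation experiments.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n
    male = rng.random(n) < 0.5
    state = SDPopulationState(
        male=male,
        y_long=np.zeros(n, dtype=bool),
        x1_long=np.zeros(n, dtype=bool),
        x2_long=np.zeros(n, dtype=bool),
        ancestry=np.zeros(n),
        mito_donor=np.zeros(n, dtype=bool),
    )
    if introduce_long_y:
        males = np.flatnonzero(male)
        if males.size < introduce_long_y:
            raise ValueError("fewer males than requested introductions")
        chosen = rng.choice(males, introduce_long_y, replace=False)
        state.y_long[chosen] = True
    return state


def offspring_sex_probability(
    y_long: bool, x_long: bool, d: float, is_male: bool = True
) -> float:
    """P(offspring is male) given the father's sex-chromosome classes.

    Distortion acts only in the male germline: a long-Y father with a short
    X sires males:females at (1+d):1, so P(male) = (1+d)/(2+d); a long X
    fully counteracts the drive and restores 1/2.
    """
    if not is_male:
        raise ValueError("offspring sex probability is defined for fathers only")
    if y_long and not x_long:
        return (1.0 + d) / (2.0 + d)
    return 0.5


def _viability_weights(state: SDPopulationState, params: SDParams) -> np.ndarray:
    if params.s_xhi == 0.0 and params.s_mito == 0.0:
        return np.ones(state.n)
    anc = state.ancestry
    x1 = state.x1_long.astype(float)
    x2 = state.x2_long.astype(float)
    h_x = np.where(
        state.male,
        np.abs(x1 - anc),
        0.5 * (np.abs(x1 - anc) + np.abs(x2 - anc)),
    )
    h_m = np.abs(state.mito_donor.astype(float) - anc)
    w = (1.0 - params.s_xhi * h_x) * (1.0 - params.s_mito * h_m)
    return np.clip(w, 0.0, None)


def step_generation(
    state: SDPopulationState, params: SDParams, rng: np.random.Generator
) -> SDPopulationState:
    """Advance one non-overlapping Wright–Fisher generation.

    Parents are sampled within sex with probability proportional to their
    viability weight (fertility-equivalent selection); sex-chromosome and
    mitochondrial transmission is Mendelian/uniparental; migration then
    replaces Poisson(Nm) random residents with donor individuals.
    """
    n = params.n
    males = np.flatnonzero(state.male)
    females = np.flatnonzero(~state.male)
    if males.size == 0 or females.size == 0:
        raise ExtinctionError("one sex is extinct")

    if params.s_xhi == 0.0 and params.s_mito == 0.0:
        mothers = females[rng.integers(0, females.size, n)]
        fathers = males[rng.integers(0, males.size, n)]
    else:
        w = _viability_weights(state, params)
        w_f, w_m = w[females], w[males]
        p_f = (
            w_f / w_f.sum()
            if w_f.sum() > 0
            else np.full(females.size, 1 / females.size)
        )
        p_m = (
            w_m / w_m.sum() if w_m.sum() > 0 else np.full(males.size, 1 / males.size)
        )
        mothers = rng.choice(females, n, p=p_f)
        fathers = rng.choice(males, n, p=p_m)

    distorting = state.y_long[fathers] & ~state.x1_long[fathers]
    p_male = np.where(distorting, (1.0 + params.d) / (2.0 + params.d), 0.5)
    child_male = rng.random(n) < p_male

    # maternal X gamete: one of the mother's two copies
    pick2 = rng.random(n) < 0.5
    mat_x = np.where(pick2, state.x2_long[mothers], state.x1_long[mothers])

    y_long = np.where(child_male, state.y_long[fathers], False)
    x1 = np.where(child_male, mat_x, state.x1_long[fathers])  # sons: maternal X
    x2 = np.where(child_male, False, mat_x)  # daughters: paternal + maternal

    ancestry = 0.5 * (state.ancestry[mothers] + state.ancestry[fathers])
    mito = state.mito_donor[mothers]

    new = SDPopulationState(
        male=child_male,
        y_long=y_long.astype(bool),
        x1_long=x1.astype(bool),
        x2_long=x2.astype(bool),
        ancestry=ancestry,
        mito_donor=mito.astype(bool),
    )

    k = rng.poisson(params.nm)
    if k > 0:
        k = min(k, n)
        idx = rng.choice(n, k, replace=False)
        new.male[idx] = rng.random(k) < 0.5
        new.y_long[idx] = new.male[idx]  # only males carry a Y
        new.x1_long[idx] = True
        new.x2_long[idx] = ~new.male[idx]
        new.ancestry[idx] = 1.0
        new.mito_donor[idx] = True
    return new


@dataclasses.dataclass
class FixationResult:
    """Per-replicate fixation outcomes and summaries."""

    table: pd.DataFrame  # replicate, y_fix_gen, x_fix_gen, censored flags, finals
    params: SDParams
    trajectories: pd.DataFrame | None = None

    def median_y_fixation_in_n(self) -> float:
        """Median long-Y fixation generation in units of N (censored reps
        count as max_generations, a conservative upper bound)."""
        g = self.table["y_fix_gen"].fillna(self.params.max_generations)
        return float(np.median(g) / self.params.n)

    def p_y_fixed_by(self, generations: float) -> float:
        fixed = self.table["y_fix_gen"].notna() & (
            self.table["y_fix_gen"] <= generations
        )
        return float(fixed.mean())

    def x_censored_fraction(self) -> float:
        return float(self.table["x_fix_gen"].isna().mean())


def replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    """Counter-based per-replicate stream: same replicate, same stream."""
    return np.random.default_rng([master_seed, replicate])


def run_replicates(
    params: SDParams,
    stop_when: str = "both",
    record_every: int = 0,
    introduce_long_y: int = 0,
) -> FixationResult:
    """Run independent replicates and collect fixation outcomes.

    ``stop_when`` is 'y' (stop once long-Y is fixed among males, or lost in
    a closed population), 'both' (wait for long-X fixation too) or 'max'.
    Once fixed, a class cannot revert (migrants only ever carry long
    haplotypes), so early stopping is exact.
    """
    if stop_when not in {"y", "both", "max"}:
        raise ValueError("stop_when must be 'y', 'both' or 'max'")
    rows = []
    trajs = []
    for rep in range(params.replicates):
        rng = replicate_rng(params.seed, rep)
        state = initialize_population(params, rng, introduce_long_y=introduce_long_y)
        y_fix = x_fix = None
        extinct = False
        for gen in range(1, params.max_generations + 1):
            try:
                state = step_generation(state, params, rng)
            except ExtinctionError:
                extinct = True
                break
            fy = state.freq_long_y()
            fx = state.freq_long_x()
            if record_every and gen % record_every == 0:
                trajs.append(
                    (
                        rep,
                        gen,
                        fy,
                        fx,
                        state.mean_ancestry(),
                        state.freq_donor_mito(),
                    )
                )
            if y_fix is None and fy == 1.0:
                y_fix = gen
            if x_fix is None and fx == 1.0:
                x_fix = gen
            lost = params.nm == 0 and fy == 0.0 and fx == 0.0
            if stop_when == "y" and (y_fix is not None or lost):
                break
            if stop_when == "both" and (
                (y_fix is not None and x_fix is not None) or lost
            ):
                break
        rows.append(
            (
                rep,
                y_fix,
                x_fix,
                y_fix is None,
                x_fix is None,
                extinct,
                state.freq_long_y(),
                state.freq_long_x(),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "replicate",
            "y_fix_gen",
            "x_fix_gen",
            "y_censored",
            "x_censored",
            "extinct",
            "final_freq_long_y",
            "final_freq_long_x",
        ],
    )
    table["y_fix_gen"] = table["y_fix_gen"].astype(float)
    table["x_fix_gen"] = table["x_fix_gen"].astype(float)
    traj_df = (
        pd.DataFrame(
            trajs,
            columns=[
                "replicate",
                "generation",
                "freq_long_y",
                "freq_long_x",
                "mean_ancestry",
                "freq_donor_mito",
            ],
        )
        if record_every
        else None
    )
    return FixationResult(table=table, params=params, trajectories=traj_df)
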