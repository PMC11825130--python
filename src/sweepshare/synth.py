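"""Synthetic multi-population datasets with known sweep-sharing truth.

Neutral haplotypes come from coalescent simulation under a
piecewise-constant demography. Sweep signals are emulated by a parametric
transform of the neutral matrix (local SNP thinning plus resampling of
derived carriers to extreme frequencies), so the true sweep locations and
sharing structure are exact by construction. Unfolded-SFS count tables
with a known true adaptive proportion curve are generated by inverting
the per-bin alpha estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .scan import HaplotypeMatrix

DEFAULT_MU = 3e-8
DEFAULT_R = 1.6e-8


@dataclass
class Demography:
    """Piecewise-constant diploid demography.

    ``epochs`` is an ordered list of ``(start_generation, Ne)`` pairs with
    start generations strictly increasing from 0 (present) into the past.
    """

    epochs: list[tuple[float, float]]
    mu: float = DEFAULT_MU
    r: float = DEFAULT_R

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("at least one epoch required")
        starts = [t for t, _ in self.epochs]
        if starts[0] != 0:
            raise ValueError("first epoch must start at generation 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start generations must be strictly increasing")
        if any(ne <= 0 for _, ne in self.epochs):
            raise ValueError("all Ne must be > 0")
        if self.mu < 0 or self.r < 0:
            raise ValueError("mu and r must be >= 0")

    def to_msprime(self) -> msprime.Demography:
        dem = msprime.Demography()
        dem.add_population(name="pop0", initial_size=self.epochs[0][1])
        for start, ne in self.epochs[1:]:
            dem.add_population_parameters_change(time=start, initial_size=ne)
        return dem

    @classmethod
    def constant(cls, ne: float, mu: float = DEFAULT_MU, r: float = DEFAULT_R) -> "Demography":
        return cls(epochs=[(0.0, float(ne))], mu=mu, r=r)

    @classmethod
    def from_dict(cls, d: dict) -> "Demography":
        return cls(
            epochs=[(float(t), float(ne)) for t, ne in d["epochs"]],
            mu=float(d.get("mu", DEFAULT_MU)),
            r=float(d.get("r", DEFAULT_R)),
        )


@dataclass
class SweepScenario:
    """Parametric hard-sweep footprint shared by one or more populations."""

    center_bp: int
    footprint_halfwidth_bp: float
    drop_max: float
    extreme_max: float
    carrier_populations: frozenset[str]
    scenario_id: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.drop_max <= 1:
            raise ValueError("drop_max must be in [0, 1]")
        if not 0 <= self.extreme_max <= 1:
            raise ValueError("extreme_max must be in [0, 1]")
        if self.footprint_halfwidth_bp < 0:
            raise ValueError("footprint halfwidth must be >= 0")
        if not self.carrier_populations:
            raise ValueError("carrier_populations must be non-empty")
        self.carrier_populations = frozenset(self.carrier_populations)


@dataclass
class TruthTable:
    """One row per scenario: id, carriers, center, footprint halfwidth."""

    rows: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_scenarios(cls, scenarios: list[SweepScenario]) -> "TruthTable":
        return cls(
            pd.DataFrame(
                {
                    "scenario_id": [s.scenario_id for s in scenarios],
                    "carriers": [",".join(sorted(s.carrier_populations)) for s in scenarios],
                    "center_bp": [s.center_bp for s in scenarios],
                    "footprint_halfwidth_bp": [s.footprint_halfwidth_bp for s in scenarios],
                }
            )
        )


# ---------------------------------------------------------------------------
# neutral simulation
# ---------------------------------------------------------------------------


def simulate_neutral_haplotypes(
    demog: Demography, n_hap: int, L: int, seed: int, chrom: str = "1"
) -> HaplotypeMatrix:
    """Coalescent haplotypes at biallelic polymorphic sites.

    Sites with more than two alleles after mutation are dropped; derived
    state is coded 1. Positions are 1-based and strictly increasing.
    """
    if n_hap < 2:
        raise ValueError("n_hap must be >= 2")
    if L < 1e5:
        raise ValueError("L must be >= 1e5")
    ts = msprime.sim_ancestry(
        samples=[msprime.SampleSet(n_hap, ploidy=1)],
        demography=demog.to_msprime(),
        sequence_length=float(L),
        recombination_rate=demog.r,
        random_seed=seed,
        ploidy=2,
    )
    ts = msprime.sim_mutations(ts, rate=demog.mu, random_seed=seed + 7_654_321)
    G = ts.genotype_matrix()  # sites x haplotypes, allele indices
    positions = np.array([s.position for s in ts.sites()], dtype=np.int64) + 1
    biallelic = G.max(axis=1) == 1
    counts = G.sum(axis=1)
    poly = (counts > 0) & (counts < n_hap)
    keep = biallelic & poly
    return HaplotypeMatrix(
        chrom=chrom, L=int(L), positions=positions[keep], derived=G[keep].T
    )


# ---------------------------------------------------------------------------
# sweep injection
# ---------------------------------------------------------------------------


def inject_sweep(hap: HaplotypeMatrix, scenario: SweepScenario, seed: int) -> HaplotypeMatrix:
    """Apply the parametric sweep transform around ``scenario.center_bp``.

    A SNP at distance d < L_s from the center is dropped with probability
    ``drop_max * (1 - d/L_s)``; if retained, with probability
    ``extreme_max * (1 - d/L_s)`` its derived carriers are resampled to a
    uniformly chosen set of size 1 or n_hap - 1 (equal probability).
    SNPs at d >= L_s are untouched.
    """
    if not 1 <= scenario.center_bp <= hap.L:
        raise ValueError("sweep center must lie within the chromosome")
    Ls = scenario.footprint_halfwidth_bp
    if Ls == 0 or hap.n_sites == 0:
        return hap
    rng = np.random.default_rng(seed)
    d = np.abs(hap.positions - scenario.center_bp).astype(float)
    in_fp = d < Ls
    taper = np.zeros(hap.n_sites)
    taper[in_fp] = 1.0 - d[in_fp] / Ls

    drop = in_fp & (rng.random(hap.n_sites) < scenario.drop_max * taper)
    keep_idx = np.flatnonzero(~drop)

    derived = hap.derived[:, keep_idx].copy()
    taper_kept = taper[keep_idx]
    extremize = rng.random(keep_idx.size) < scenario.extreme_max * taper_kept
    n = hap.n_hap
    for j in np.flatnonzero(extremize):
        count = 1 if rng.random() < 0.5 else n - 1
        carriers = rng.choice(n, size=count, replace=False)
        derived[:, j] = 0
        derived[carriers, j] = 1
    return HaplotypeMatrix(
        chrom=hap.chrom, L=hap.L, positions=hap.positions[keep_idx], derived=derived
    )


# ---------------------------------------------------------------------------
# multi-population datasets
# ---------------------------------------------------------------------------


@dataclass
class PopulationSpec:
    label: str
    subspecies: str
    n_hap: int
    demography: Demography
    replicate: bool = False


@dataclass
class DatasetConfig:
    """Declarative description of a multi-population synthetic dataset."""

    L: int
    populations: list[PopulationSpec]
    scenarios: list[SweepScenario]
    chrom: str = "1"

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetConfig":
        pops = [
            PopulationSpec(
                label=p["label"],
                subspecies=p.get("subspecies", "na"),
                n_hap=int(p["n_hap"]),
                demography=Demography.from_dict(p["demography"]),
                replicate=bool(p.get("replicate", False)),
            )
            for p in d["populations"]
        ]
        scens = [
            SweepScenario(
                center_bp=int(s["center_bp"]),
                footprint_halfwidth_bp=float(s["footprint_halfwidth_bp"]),
                drop_max=float(s["drop_max"]),
                extreme_max=float(s["extreme_max"]),
                carrier_populations=frozenset(s["carriers"]),
                scenario_id=str(s.get("id", "")),
            )
            for s in d.get("scenarios", [])
        ]
        for i, s in enumerate(scens):
            if not s.scenario_id:
                s.scenario_id = f"s{i + 1}"
        return cls(
            L=int(d["L"]),
            populations=pops,
            scenarios=scens,
            chrom=str(d.get("chrom", "1")),
        )


def replicate_labels(label: str) -> tuple[str, str]:
    return f"{label}_rep1", f"{label}_rep2"


def generate_multipop_dataset(
    config: DatasetConfig, seed: int
) -> tuple[dict[str, HaplotypeMatrix], TruthTable]:
    """Simulate every population and inject shared scenarios.

    Replicate-flagged populations are simulated once at twice the sample
    size and split into disjoint halves; each half receives the
    population's scenarios (same centers, independent injection noise), so
    replicate pairs share all of the population's sweeps by construction.
    """
    labels = {p.label for p in config.populations}
    for s in config.scenarios:
        unknown = s.carrier_populations - labels
        if unknown:
            raise ValueError(f"scenario {s.scenario_id} references unknown populations {sorted(unknown)}")

    root = np.random.default_rng(seed)
    out: dict[str, HaplotypeMatrix] = {}
    for p in config.populations:
        sim_seed = int(root.integers(1, 2**31 - 1))
        scens = [s for s in config.scenarios if p.label in s.carrier_populations]
        if p.replicate:
            full = simulate_neutral_haplotypes(
                p.demography, 2 * p.n_hap, config.L, sim_seed, chrom=config.chrom
            )
            halves = (
                full.take_haplotypes(np.arange(p.n_hap)),
                full.take_haplotypes(np.arange(p.n_hap, 2 * p.n_hap)),
            )
            for name, half in zip(replicate_labels(p.label), halves):
                for s in scens:
                    half = inject_sweep(half, s, int(root.integers(1, 2**31 - 1)))
                out[name] = half
        else:
            hap = simulate_neutral_haplotypes(
                p.demography, p.n_hap, config.L, sim_seed, chrom=config.chrom
            )
            for s in scens:
                hap = inject_sweep(hap, s, int(root.integers(1, 2**31 - 1)))
            out[p.label] = hap
    return out, TruthTable.from_scenarios(config.scenarios)


# ---------------------------------------------------------------------------
# uSFS count tables with known truth
# ---------------------------------------------------------------------------


@dataclass
class UsfsCounts:
    """Per-frequency-bin selected/neutral polymorphism and fixation counts.

    Bins are i = 1..n-1 with derived-allele frequency x_i = i/n. ``p`` are
    selected-class polymorphic counts, ``p0`` neutral-class counts; ``d``
    and ``d0`` the corresponding fixed-difference totals (subscript 0 =
    neutral throughout).
    """

    n: int
    p: np.ndarray
    p0: np.ndarray
    d: float
    d0: float
    labels: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.p0 = np.asarray(self.p0, dtype=float)
        if self.p.shape != (self.n - 1,) or self.p0.shape != (self.n - 1,):
            raise ValueError("p and p0 must have n-1 bins")
        if np.any(self.p < 0) or np.any(self.p0 < 0) or self.d < 0 or self.d0 < 0:
            raise ValueError("counts must be >= 0")

    @property
    def x(self) -> np.ndarray:
        return np.arange(1, self.n) / self.n

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"bin": np.arange(1, self.n), "x": self.x, "p": self.p, "p0": self.p0}
        )
        df.attrs["d"] = self.d
        df.attrs["d0"] = self.d0
        return df


def alpha_curve(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """Asymptotic adaptive-proportion curve a + b * exp(-c * x)."""
    return a + b * np.exp(-c * np.asarray(x, dtype=float))


def generate_usfs_counts(
    a: float,
    b: float,
    c: float,
    d0: float,
    d: float,
    theta0: float,
    n: int,
    seed: int,
    labels: dict | None = None,
) -> UsfsCounts:
    """Poisson uSFS counts whose expected per-bin alpha equals the curve.

    Neutral bins have intensity theta0/i; selected bins have intensity
    (d/d0) * (1 - alpha(x_i)) * theta0/i, which plugs back into
    alpha_i = 1 - (d0/d) * (p_i/p0_i) with expectation alpha(x_i).
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    if d0 <= 0 or d <= 0:
        raise ValueError("d0 and d must be > 0")
    x = np.arange(1, n) / n
    alpha = alpha_curve(x, a, b, c)
    if np.any(1 - alpha < 0):
        raise ValueError("parameters imply negative expected counts (alpha > 1)")
    rng = np.random.default_rng(seed)
    lam0 = theta0 / np.arange(1, n)
    lam = (d / d0) * (1 - alpha) * lam0
    return UsfsCounts(
        n=n,
        p=rng.poisson(lam).astype(float),
        p0=rng.poisson(lam0).astype(float),
        d=float(d),
        d0=float(d0),
        labels=dict(labels or {}),
        metadata={
            "true_a": a,
            "true_b": b,
            "true_c": c,
            "true_alpha_inf": float(a + b * np.exp(-c)),
        },
    )
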