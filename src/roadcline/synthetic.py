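"""Synthetic study generator with known truth.

Emulates the full data-generating process assumed by the analysis: Poisson
site abundances declining log-linearly with distance to the city center, a
binomial melanic split whose logit also declines with distance, binomial
point counts and Bernoulli camera detection histories with
quadratic-in-temperature detection, Bernoulli DOR morph records, a
DAG-structured road/landscape covariate model with a logistic mortality
outcome, and 2x2 citizen-science classification tables.

Every generator takes an integer seed and is bit-reproducible.  Defaults are
the study conditions: 41 sites spanning 0.93-11.3 km (24 with cameras),
5 point-count surveys per site and 263 camera days per camera site (the
design medians), 141 DOR records, and generating coefficients equal to the
published posterior means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import LatentAbundance, RiskDataset, SiteDataset, Standardizer
from .tables import ContingencyTable2x2

__all__ = [
    "TruthParams",
    "SurveyDesign",
    "simulate_squirrel_landscape",
    "simulate_observations",
    "simulate_dor_records",
    "simulate_study",
    "RiskTruth",
    "simulate_risk_dataset",
    "make_citizen_table",
]


@dataclass(frozen=True)
class TruthParams:
    """Generating coefficients for the living-squirrel and DOR submodels.

    Slopes are per standard deviation of distance to city center.  The
    abundance pair (beta0_N, beta1_N) parameterizes log mean total abundance;
    (beta0_M, beta1_M) the logit proportion melanic among living squirrels;
    ``det_*`` the logit-scale quadratic-in-temperature detection
    coefficients per morph; (alpha_D, beta_D) the logit proportion melanic
    among road-killed squirrels.
    """

    beta0_N: float = 2.58
    beta1_N: float = -0.62
    beta0_M: float = -0.85
    beta1_M: float = -0.80
    det_melanic: tuple[float, float, float] = (-2.16, -0.058, -0.34)
    det_gray: tuple[float, float, float] = (-1.53, -0.019, -0.39)
    alpha_D: float = -1.36
    beta_D: float = -0.22
    distance_range_km: tuple[float, float] = (0.93, 11.3)

    def __post_init__(self) -> None:
        lo, hi = self.distance_range_km
        if not (0 < lo < hi):
            raise ValueError("distance range must satisfy 0 < min < max")
        vals = [
            self.beta0_N, self.beta1_N, self.beta0_M, self.beta1_M,
            *self.det_melanic, *self.det_gray, self.alpha_D, self.beta_D,
        ]
        if not np.all(np.isfinite(vals)):
            raise ValueError("all generating coefficients must be finite")


@dataclass(frozen=True)
class SurveyDesign:
    """Repeat-survey effort per site.

    ``surveys_per_site`` and ``camera_days`` are either a single integer
    applied to every (camera) site or a per-site sequence.  When
    ``randomize`` is set, effort is drawn per site over the study's printed
    ranges (2-7 surveys centered on 5; 46-379 camera days centered near 263).
    """

    surveys_per_site: int | tuple[int, ...] = 5
    camera_days: int | tuple[int, ...] = 263
    n_camera_sites: int = 24
    randomize: bool = False

    def surveys_for(self, n_sites: int, rng: np.random.Generator) -> np.ndarray:
        if self.randomize:
            return rng.choice(
                np.arange(2, 8),
                size=n_sites,
                p=[0.05, 0.10, 0.15, 0.40, 0.15, 0.15],
            )
        arr = np.broadcast_to(np.asarray(self.surveys_per_site, dtype=int), (n_sites,))
        if (arr < 1).any():
            raise ValueError("every site needs at least one point-count survey")
        return arr.copy()

    def camera_days_for(self, n_camera: int, rng: np.random.Generator) -> np.ndarray:
        if self.randomize:
            frac = rng.beta(2.2, 1.3, size=n_camera)  # median near 263 of 46-379
            return np.rint(46 + frac * (379 - 46)).astype(int)
        arr = np.broadcast_to(np.asarray(self.camera_days, dtype=int), (n_camera,))
        if (arr < 1).any():
            raise ValueError("camera sites need at least one active day")
        return arr.copy()


def _seasonal_temperature(day_of_year: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # Mean daily temperature: annual sinusoid (coldest late January) + weather noise.
    return (
        9.0
        - 13.0 * np.cos(2 * np.pi * (day_of_year - 28) / 365.0)
        + rng.normal(0.0, 3.0, size=day_of_year.shape)
    )


def simulate_squirrel_landscape(
    truth: TruthParams,
    n_sites: int,
    seed: int,
    n_camera_sites: int | None = None,
) -> tuple[pd.DataFrame, list[LatentAbundance], Standardizer]:
    """Draw site locations and the latent morph abundances at each site.

    Distances are uniform over ``truth.distance_range_km`` and standardized;
    ``N_total ~ Poisson(exp(beta0_N + beta1_N z))`` and
    ``N_melanic ~ Binomial(N_total, expit(beta0_M + beta1_M z))``.

    Returns the site table (with ``camera_flag`` set on a random subset of
    ``n_camera_sites`` sites), the latent abundances, and the distance
    standardizer.
    """
    if n_sites < 2:
        raise ValueError("need at least two sites")
    rng = np.random.default_rng(seed)
    lo, hi = truth.distance_range_km
    distance = rng.uniform(lo, hi, size=n_sites)
    std = Standardizer.fit(distance)
    z = std.transform(distance)

    lam = np.exp(truth.beta0_N + truth.beta1_N * z)
    p_mel = expit(truth.beta0_M + truth.beta1_M * z)
    n_total = rng.poisson(lam)
    n_mel = rng.binomial(n_total, p_mel)

    if n_camera_sites is None:
        n_camera_sites = min(24, n_sites)
    cam_sites = rng.choice(n_sites, size=min(n_camera_sites, n_sites), replace=False)
    camera_flag = np.zeros(n_sites, dtype=int)
    camera_flag[cam_sites] = 1

    sites = pd.DataFrame(
        {"site": np.arange(n_sites), "distance_km": distance, "camera_flag": camera_flag}
    )
    latents = [
        LatentAbundance(site=i, n_total=int(n_total[i]), n_melanic=int(n_mel[i]))
        for i in range(n_sites)
    ]
    for la in latents:
        la.validate()
    return sites, latents, std


def simulate_observations(
    truth: TruthParams,
    sites: pd.DataFrame,
    latents: list[LatentAbundance],
    design: SurveyDesign,
    seed: int,
    distance_std: Standardizer | None = None,
) -> SiteDataset:
    """Generate point counts and camera detection histories given the latents.

    Counts are ``Binomial(N_k, p)`` per survey and morph; camera days are
    ``Bernoulli(1 - (1 - p)^N_k)``; detection ``p`` is the quadratic-in-
    temperature logit per morph.  Survey and camera temperatures are drawn
    from a seasonal sinusoid plus noise, then standardized over the pooled
    occasions.
    """
    n_sites = len(sites)
    if len(latents) != n_sites:
        raise ValueError("latent abundances do not match the site table")
    rng = np.random.default_rng(seed)
    n_surv = design.surveys_for(n_sites, rng)

    cam_site_ids = sites.loc[sites["camera_flag"] == 1, "site"].to_numpy()
    n_days = design.camera_days_for(len(cam_site_ids), rng)

    # Raw occasion temperatures (counts span fall+spring survey windows,
    # cameras run consecutively from a fall start date).
    count_rows = []
    for i, sid in enumerate(sites["site"].to_numpy()):
        days = rng.integers(0, 365, size=n_surv[i])
        temps = _seasonal_temperature(days.astype(float), rng)
        for j in range(n_surv[i]):
            count_rows.append((sid, j, temps[j]))
    cam_rows = []
    for i, sid in enumerate(cam_site_ids):
        start = rng.integers(230, 300)
        days = (start + np.arange(n_days[i])) % 365
        temps = _seasonal_temperature(days.astype(float), rng)
        for d in range(n_days[i]):
            cam_rows.append((sid, d, temps[d]))

    pooled = np.array([r[2] for r in count_rows] + [r[2] for r in cam_rows])
    temp_std = Standardizer.fit(pooled)

    n_by_site = {la.site: (la.n_melanic, la.n_total - la.n_melanic) for la in latents}

    def det_p(coefs, t):
        a0, a1, a2 = coefs
        return expit(a0 + a1 * t + a2 * t * t)

    counts = []
    for sid, j, temp in count_rows:
        t = float(temp_std.transform(temp))
        row = [sid, j, t]
        for coefs, nk in zip((truth.det_melanic, truth.det_gray), n_by_site[sid]):
            row.append(int(rng.binomial(nk, det_p(coefs, t))))
        counts.append(row)
    cameras = []
    for sid, d, temp in cam_rows:
        t = float(temp_std.transform(temp))
        row = [sid, d, t]
        for coefs, nk in zip((truth.det_melanic, truth.det_gray), n_by_site[sid]):
            p_star = 1.0 - (1.0 - det_p(coefs, t)) ** nk
            row.append(int(rng.random() < p_star))
        cameras.append(row)

    if distance_std is None:
        distance_std = Standardizer.fit(sites["distance_km"].to_numpy())
    return SiteDataset(
        sites=sites.copy(),
        counts=pd.DataFrame(
            counts, columns=["site", "survey", "temperature_std", "count_melanic", "count_gray"]
        ),
        cameras=pd.DataFrame(
            cameras, columns=["site", "day", "temperature_std", "det_melanic", "det_gray"]
        ),
        distance_std=distance_std,
        temperature_std=temp_std,
    )


def simulate_dor_records(truth: TruthParams, n_records: int, seed: int) -> pd.DataFrame:
    """Draw DOR squirrels: uniform distances, morph ~ Bernoulli(cline logit).

    Returns a DataFrame with columns ``distance_km`` and ``morph``
    (1 = melanic); distances are standardized with the sample's own
    constants when the model is fit.
    """
    if n_records < 1:
        raise ValueError("need at least one DOR record")
    rng = np.random.default_rng(seed)
    lo, hi = truth.distance_range_km
    distance = rng.uniform(lo, hi, size=n_records)
    z = Standardizer.fit(distance).transform(distance) if n_records > 1 else np.zeros(1)
    p = expit(truth.alpha_D + truth.beta_D * z)
    morph = (rng.random(n_records) < p).astype(int)
    return pd.DataFrame({"distance_km": distance, "morph": morph})


def simulate_study(
    truth: TruthParams,
    seed: int,
    n_sites: int = 41,
    design: SurveyDesign | None = None,
    n_dor: int = 141,
) -> tuple[SiteDataset, pd.DataFrame, list[LatentAbundance]]:
    """One full synthetic field season at study scale (convenience wrapper)."""
    design = design or SurveyDesign()
    ss = np.random.SeedSequence(seed)
    s_land, s_obs, s_dor = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    sites, latents, dist_std = simulate_squirrel_landscape(
        truth, n_sites, s_land, n_camera_sites=design.n_camera_sites
    )
    data = simulate_observations(truth, sites, latents, design, s_obs, distance_std=dist_std)
    dor = simulate_dor_records(truth, n_dor, s_dor)
    return data, dor, latents


# ---------------------------------------------------------------------------
# Road/landscape risk dataset with DAG-structured covariates
# ---------------------------------------------------------------------------

# Registered nodes and the natural-scale mapping of each node's standardized
# structural value x.  "latent" nodes never appear in the output table.
_RISK_NODES = (
    "distance",
    "pop_density",
    "building_density",
    "forest_cover",
    "fragmentation",
    "morph_abundance",
    "speed",
    "traffic",
    "crossings",
    "habitat_split",
    "mortality",
)
_LATENT_NODES = {"building_density", "morph_abundance", "mortality"}


@dataclass(frozen=True)
class RiskTruth:
    """Structural-equation truth for the risk dataset generator.

    ``edges`` maps (parent, child) to the linear coefficient on the parent's
    standardized structural value; ``noise_sd`` gives each node's Gaussian
    innovation SD; ``outcome_coefs`` act on the analysis scales used by the
    regressions (log units for traffic/pop_density/fragmentation, the raw
    [0,1] value for habitat_split, the binary indicator for crossings, and
    ~8 mph per unit for speed).
    """

    edges: dict = field(default_factory=lambda: {
        ("distance", "pop_density"): -0.8,
        ("distance", "forest_cover"): 0.6,
        ("distance", "fragmentation"): 0.5,
        ("distance", "morph_abundance"): -0.8,
        ("forest_cover", "morph_abundance"): 0.3,
        ("pop_density", "building_density"): 0.9,
        ("pop_density", "speed"): -0.6,
        ("pop_density", "traffic"): 0.7,
        ("building_density", "crossings"): 0.8,
        ("forest_cover", "crossings"): 0.6,
        ("fragmentation", "habitat_split"): 0.9,
    })
    noise_sd: dict = field(default_factory=lambda: {
        "pop_density": 0.6,
        "building_density": 0.45,
        "forest_cover": 0.8,
        "fragmentation": 0.85,
        "morph_abundance": 0.6,
        "speed": 0.8,
        "traffic": 0.7,
        "crossings": 0.0,
        "habitat_split": 0.8,
    })
    outcome_intercept: float = -2.0
    outcome_coefs: dict = field(default_factory=lambda: {
        "speed": 0.0,
        "traffic": 0.32,
        "crossings": 0.8,
        "habitat_split": 0.0,
        "morph_abundance": 0.4,
    })
    distance_range_km: tuple[float, float] = (0.93, 11.3)

    @classmethod
    def default_gray(cls) -> "RiskTruth":
        return cls()

    @classmethod
    def default_melanic(cls) -> "RiskTruth":
        return cls(outcome_coefs={
            "speed": 0.0,
            "traffic": 0.0,
            "crossings": 0.0,
            "habitat_split": 1.89,
            "morph_abundance": 0.4,
        })


def _risk_structural_sample(truth: RiskTruth, n: int, rng: np.random.Generator) -> pd.DataFrame:
    import networkx as nx

    for parent, child in truth.edges:
        for node in (parent, child):
            if node not in _RISK_NODES:
                raise ValueError(f"unknown DAG node {node!r}")
    g = nx.DiGraph(list(truth.edges))
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("risk structural equations contain a cycle")

    lo, hi = truth.distance_range_km
    d = rng.uniform(lo, hi, size=n)
    x = {"distance": (d - d.mean()) / d.std(ddof=1)}
    order = [v for v in nx.topological_sort(g) if v != "distance"]
    # Nodes with no structural parents still get innovations if they have noise.
    for node in _RISK_NODES:
        if node in ("distance", "mortality") or node in x:
            continue
        if node not in order:
            order.append(node)
    for node in order:
        if node == "mortality":
            continue
        val = np.zeros(n)
        for parent in g.predecessors(node) if node in g else []:
            val = val + truth.edges[(parent, node)] * x[parent]
        sd = truth.noise_sd.get(node, 1.0)
        if node == "crossings":
            x[node] = (rng.random(n) < expit(-0.2 + val)).astype(float)
        else:
            x[node] = val + rng.normal(0.0, sd, size=n)

    natural = pd.DataFrame({
        "speed": np.clip(35.0 + 8.0 * x["speed"], 15.0, 65.0),
        "traffic": np.exp(8.0 + x["traffic"]),
        "crossings": x["crossings"].astype(int),
        "habitat_split": expit(-1.2 + x["habitat_split"]),
        "pop_density": np.exp(6.5 + x["pop_density"]),
        "forest_cover": expit(-0.5 + 0.9 * x["forest_cover"]),
        "fragmentation": np.exp(2.2 + 0.7 * x["fragmentation"]),
    })

    lp = np.full(n, truth.outcome_intercept)
    analysis_scale = {
        "speed": x["speed"],
        "traffic": x["traffic"],          # = log(traffic) - 8
        "pop_density": x["pop_density"],  # = log(pop_density) - 6.5
        "fragmentation": x["fragmentation"],
        "crossings": x["crossings"],
        "habitat_split": natural["habitat_split"].to_numpy(),
        "forest_cover": x["forest_cover"],
        "morph_abundance": x["morph_abundance"],
        "distance": x["distance"],
    }
    for node, coef in truth.outcome_coefs.items():
        if node not in analysis_scale:
            raise ValueError(f"unknown outcome covariate {node!r}")
        lp = lp + coef * analysis_scale[node]
    natural.insert(0, "outcome", (rng.random(n) < expit(lp)).astype(int))
    return natural


def simulate_risk_dataset(
    risk_truth: RiskTruth,
    n_per_group: int,
    seed: int,
    morph: str = "gray",
    balanced: bool = True,
) -> RiskDataset:
    """Generate DOR/reference locations with DAG-structured covariates.

    With ``balanced=True`` (the matched design), sampling continues until
    ``n_per_group`` locations of each outcome class are collected, mirroring
    the study's equal case/reference construction.  With ``balanced=False``
    the first ``2*n_per_group`` locations are returned at the model's own
    prevalence.
    """
    if n_per_group < 10:
        raise ValueError("n_per_group must be at least 10")
    rng = np.random.default_rng(seed)
    if not balanced:
        frame = _risk_structural_sample(risk_truth, 2 * n_per_group, rng)
        return RiskDataset(frame=frame.reset_index(drop=True), morph=morph, balanced=False)

    cases, refs = [], []
    for _ in range(400):
        batch = _risk_structural_sample(risk_truth, max(4 * n_per_group, 500), rng)
        cases.append(batch[batch["outcome"] == 1])
        refs.append(batch[batch["outcome"] == 0])
        if (sum(len(c) for c in cases) >= n_per_group
                and sum(len(r) for r in refs) >= n_per_group):
            break
    else:  # pragma: no cover - pathological truth values
        raise RuntimeError("could not collect the requested case/reference counts")
    frame = pd.concat(
        [pd.concat(cases).head(n_per_group), pd.concat(refs).head(n_per_group)],
        ignore_index=True,
    )
    frame = frame.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    return RiskDataset(frame=frame, morph=morph, balanced=True)


def make_citizen_table(
    total_melanic: int, dead_melanic: int, total_gray: int, dead_gray: int
) -> ContingencyTable2x2:
    """Build the morph x dead/alive table from classification totals."""
    return ContingencyTable2x2.from_totals(total_melanic, dead_melanic, total_gray, dead_gray)
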