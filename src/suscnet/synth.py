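"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates what matters to KL-similarity networks — the
*marginal* distribution of susceptibility values per region — not imaging
data itself.  Region mean susceptibilities follow a community model: each
of the 8 functional networks gets a community center (SD
``between_community_sd``) and regions scatter around their center (SD
``within_community_sd``), so regions in one community have more similar
distributions, giving the networks community structure, clustering above
degree-matched random graphs, and hence small-world organization.
Subjects jitter region means (SD ``subject_sd``); voxels are Gaussian
draws (SD ``region_sd``, optional skew-normal shape) with anatomically
fixed per-region voxel counts.

Group effects are planted on *disjoint* region pairs by shifting the two
endpoint means apart by ``magnitude/2`` each (or inflating one endpoint's
SD for variance effects).  Because an edge is a function of its two
region marginals, any planted effect leaks into the endpoints' other
edges; the opposite-shift construction makes the planted edge carry twice
the displacement of any collateral edge, so planted edges dominate
rankings.  The ground-truth record lists every planted pair.

Test-retest pairs reuse each subject's session-1 region means perturbed
by ``trt_noise`` and redraw voxels from an offset RNG stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import SpecError
from .roi_io import FUNCTIONAL_NETWORKS, CohortDesign, SusceptibilityROISamples

import pandas as pd

TRT_SEED_OFFSET = 1_000_003  # session-2 RNG stream offset, documented contract


@dataclass
class CovariateModel:
    """Demographics: age (years), gender (M/F), education (years)."""

    age_mean: float = 68.0
    age_sd: float = 8.0
    group_age_shift: dict[str, float] = field(default_factory=dict)
    p_female: float = 0.5
    education_mean: float = 12.0
    education_sd: float = 3.0
    #: Adds ``coef * (age - age_mean)`` to every region mean (confounding).
    age_confound_coef: float = 0.0


@dataclass
class Effect:
    """A planted group effect on a set of edges.

    ``edges`` are region-id pairs; alternatively give ``network_pair``
    (e.g. ``("DMN", "DMN")``) and ``n_edges`` to sample disjoint pairs
    within those communities.  ``kind`` is ``"mean-shift"`` (endpoint
    means pushed apart by ``magnitude`` region-SDs in total) or
    ``"variance-inflation"`` (second endpoint's SD multiplied by
    ``magnitude``).
    """

    group: str
    magnitude: float
    kind: str = "mean-shift"
    edges: tuple[tuple[int, int], ...] | None = None
    network_pair: tuple[str, str] | None = None
    n_edges: int = 10


@dataclass
class SyntheticCohortSpec:
    """All knobs of the generator; ``seed`` is mandatory."""

    seed: int
    n_regions: int = 90
    n_communities: int = 8
    groups: dict[str, int] = field(default_factory=lambda: {"HC": 20})
    voxels_per_region: tuple[int, int] = (50, 500)
    between_community_sd: float = 1.0
    within_community_sd: float = 0.3
    region_sd: float = 1.0
    subject_sd: float = 0.1
    skew: float = 0.0
    effects: tuple[Effect, ...] = ()
    covariates: CovariateModel = field(default_factory=CovariateModel)
    trt_noise: float = 0.1
    partition: dict[int, str] | None = None

    def resolved_partition(self) -> dict[int, str]:
        """Region -> community name; default: contiguous blocks over the 8 networks."""
        if self.partition is not None:
            part = {int(r): str(c) for r, c in self.partition.items()}
            if set(part) != set(range(1, self.n_regions + 1)):
                raise SpecError("partition must cover regions 1..n_regions exactly")
            return part
        names = [FUNCTIONAL_NETWORKS[i % len(FUNCTIONAL_NETWORKS)]
                 for i in range(self.n_communities)]
        blocks = np.array_split(np.arange(1, self.n_regions + 1),
                                self.n_communities)
        return {int(r): names[c] for c, block in enumerate(blocks) for r in block}


def _region_base_means(spec: SyntheticCohortSpec, rng: np.random.Generator,
                       partition: dict[int, str]) -> np.ndarray:
    communities = sorted(set(partition.values()), key=list(partition.values()).index)
    centers = {
        c: rng.normal(0.0, spec.between_community_sd) for c in communities
    }
    return np.array([
        centers[partition[r]] + rng.normal(0.0, spec.within_community_sd)
        for r in range(1, spec.n_regions + 1)
    ])


def _resolve_effects(spec: SyntheticCohortSpec, rng: np.random.Generator,
                     partition: dict[int, str]):
    """Materialize each effect's edge list; sampled edges are disjoint."""
    resolved = []
    used: set[int] = set()
    for eff in spec.effects:
        if eff.edges is not None:
            edges = [tuple(int(v) for v in e) for e in eff.edges]
        elif eff.network_pair is not None:
            net_a, net_b = eff.network_pair
            pool_a = [r for r, c in partition.items() if c == net_a and r not in used]
            pool_b = [r for r, c in partition.items() if c == net_b and r not in used]
            edges = []
            for _ in range(eff.n_edges):
                if not pool_a or not pool_b:
                    raise SpecError(
                        f"not enough free regions in {net_a}-{net_b} for "
                        f"{eff.n_edges} disjoint edges"
                    )
                a = pool_a.pop(int(rng.integers(len(pool_a))))
                if a in pool_b:
                    pool_b.remove(a)
                b = pool_b.pop(int(rng.integers(len(pool_b))))
                if b in pool_a:
                    pool_a.remove(b)
                edges.append((min(a, b), max(a, b)))
                used.update((a, b))
        else:
            raise SpecError("effect needs either edges or network_pair")
        for a, b in edges:
            if not (1 <= a <= spec.n_regions and 1 <= b <= spec.n_regions) or a == b:
                raise SpecError(f"invalid planted edge ({a}, {b})")
        resolved.append((eff, edges))
    return resolved


def _make_cohort_table(spec: SyntheticCohortSpec, rng: np.random.Generator) -> CohortDesign:
    cov = spec.covariates
    rows = []
    for group, n_sub in spec.groups.items():
        shift = cov.group_age_shift.get(group, 0.0)
        for i in range(n_sub):
            rows.append(
                {
                    "subject_id": f"{group}-{i:03d}",
                    "group": group,
                    "age": float(np.clip(rng.normal(cov.age_mean + shift, cov.age_sd), 40, 95)),
                    "gender": "F" if rng.random() < cov.p_female else "M",
                    "education": float(np.clip(rng.normal(cov.education_mean, cov.education_sd), 0, 25)),
                }
            )
    return CohortDesign(table=pd.DataFrame(rows))


def _draw_voxels(rng: np.random.Generator, mean: float, sd: float, size: int,
                 skew: float) -> np.ndarray:
    if skew == 0.0:
        return rng.normal(mean, sd, size=size)
    return sps.skewnorm.rvs(skew, loc=mean, scale=sd, size=size, random_state=rng)


def _subject_region_means(spec: SyntheticCohortSpec, rng: np.random.Generator,
                          base: np.ndarray, cohort: CohortDesign,
                          resolved_effects) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject region means and SDs after subject jitter, confounds, effects."""
    cov = spec.covariates
    n_sub = len(cohort.table)
    means = np.empty((n_sub, spec.n_regions))
    sds = np.full((n_sub, spec.n_regions), spec.region_sd)
    for s, row in cohort.table.iterrows():
        mu = base + rng.normal(0.0, spec.subject_sd, size=spec.n_regions)
        mu += cov.age_confound_coef * (row["age"] - cov.age_mean)
        for eff, edges in resolved_effects:
            if row["group"] != eff.group:
                continue
            for a, b in edges:
                if eff.kind == "mean-shift":
                    half = eff.magnitude * spec.region_sd / 2.0
                    mu[a - 1] -= half
                    mu[b - 1] += half
                elif eff.kind == "variance-inflation":
                    sds[s, b - 1] *= eff.magnitude
                else:
                    raise SpecError(f"unknown effect kind {eff.kind!r}")
        means[s] = mu
    return means, sds


def generate_cohort(spec: SyntheticCohortSpec):
    """Generate (samples, cohort, ground_truth); bit-reproducible per seed.

    ``ground_truth`` records the partition, base region means, per-subject
    means, and every planted edge with its group, kind and magnitude.
    """
    rng = np.random.default_rng(spec.seed)
    partition = spec.resolved_partition()
    base = _region_base_means(spec, rng, partition)
    lo, hi = spec.voxels_per_region
    n_vox = rng.integers(lo, hi + 1, size=spec.n_regions)
    resolved = _resolve_effects(spec, rng, partition)
    cohort = _make_cohort_table(spec, rng)
    means, sds = _subject_region_means(spec, rng, base, cohort, resolved)
    samples = _draw_all_voxels(spec, rng, cohort, means, sds, n_vox)
    shifted = sorted({r for _, edges in resolved for e in edges for r in e})
    ground_truth = {
        "partition": partition,
        "base_means": base,
        "subject_means": means,
        "voxel_counts": n_vox,
        "planted_edges": [
            {"edge": (a, b), "group": eff.group, "kind": eff.kind,
             "magnitude": eff.magnitude}
            for eff, edges in resolved
            for a, b in edges
        ],
        # every edge incident to one of these regions carries (half of) the
        # planted displacement; see the module docstring on collateral effects
        "shifted_regions": shifted,
    }
    return samples, cohort, ground_truth


def _draw_all_voxels(spec, rng, cohort, means, sds, n_vox):
    samples = []
    for s, row in cohort.table.iterrows():
        region_values = {
            r: _draw_voxels(rng, means[s, r - 1], sds[s, r - 1], int(n_vox[r - 1]),
                            spec.skew)
            for r in range(1, spec.n_regions + 1)
        }
        samples.append(
            SusceptibilityROISamples(
                subject_id=str(row["subject_id"]), region_values=region_values
            )
        )
    return samples


def generate_trt_pair(spec: SyntheticCohortSpec):
    """Two paired sessions of the same subjects.

    Session 1 is :func:`generate_cohort`.  Session 2 keeps each subject's
    region means perturbed by ``N(0, trt_noise)`` and redraws all voxels
    from an RNG seeded ``seed + TRT_SEED_OFFSET``; with ``trt_noise=0``
    the two sessions are independent draws from identical distributions.
    """
    if spec.trt_noise < 0:
        raise SpecError("trt_noise must be nonnegative")
    rng1 = np.random.default_rng(spec.seed)
    partition = spec.resolved_partition()
    base = _region_base_means(spec, rng1, partition)
    lo, hi = spec.voxels_per_region
    n_vox = rng1.integers(lo, hi + 1, size=spec.n_regions)
    resolved = _resolve_effects(spec, rng1, partition)
    cohort = _make_cohort_table(spec, rng1)
    means, sds = _subject_region_means(spec, rng1, base, cohort, resolved)
    session1 = _draw_all_voxels(spec, rng1, cohort, means, sds, n_vox)

    rng2 = np.random.default_rng(spec.seed + TRT_SEED_OFFSET)
    means2 = means + rng2.normal(0.0, spec.trt_noise, size=means.shape)
    session2 = _draw_all_voxels(spec, rng2, cohort, means2, sds, n_vox)
    return session1, session2


def generate_richclub_cohort(
    spec: SyntheticCohortSpec,
    hub_regions=None,
    hub_spread: float = 0.2,
    periphery_spread: float = 4.0,
):
    """Cohort with a planted degree-rich core.

    Hub regions get means clustered uniformly within ``hub_spread``
    region-SDs of each other, so their pairwise similarities dominate;
    peripheral means spread uniformly over ``periphery_spread``
    region-SDs.  An empty hub set falls back to the community base model.
    Returns ``(samples, hubs)``.
    """
    rng = np.random.default_rng(spec.seed)
    partition = spec.resolved_partition()
    base = _region_base_means(spec, rng, partition)
    hubs = sorted(int(h) for h in (hub_regions or []))
    if any(not 1 <= h <= spec.n_regions for h in hubs):
        raise SpecError("hub regions outside 1..n_regions")
    if hubs:
        sd = spec.region_sd
        for r in range(1, spec.n_regions + 1):
            if r in hubs:
                base[r - 1] = rng.uniform(-hub_spread / 2.0, hub_spread / 2.0) * sd
            else:
                base[r - 1] = rng.uniform(-periphery_spread / 2.0,
                                          periphery_spread / 2.0) * sd
    lo, hi = spec.voxels_per_region
    n_vox = rng.integers(lo, hi + 1, size=spec.n_regions)
    cohort = _make_cohort_table(spec, rng)
    means, sds = _subject_region_means(spec, rng, base, cohort, [])
    return _draw_all_voxels(spec, rng, cohort, means, sds, n_vox), hubs


def null_spec(seed: int, **overrides) -> SyntheticCohortSpec:
    """Convenience: a two-group cohort with no planted effects."""
    defaults = dict(
        seed=seed,
        groups={"HC": 20, "MCI-AD": 20},
        effects=(),
    )
    defaults.update(overrides)
    return SyntheticCohortSpec(**defaults)


def spec_with_effect(seed: int, n_edges: int = 10, magnitude: float = 2.0,
                     group: str = "MCI-AD", network_pair=("DMN", "DMN"),
                     **overrides) -> SyntheticCohortSpec:
    """Convenience: a two-group cohort with one planted mean-shift effect."""
    defaults = dict(
        seed=seed,
        groups={"HC": 20, "MCI-AD": 20},
        effects=(
            Effect(group=group, magnitude=magnitude, kind="mean-shift",
                   network_pair=tuple(network_pair), n_edges=n_edges),
        ),
    )
    defaults.update(overrides)
    return SyntheticCohortSpec(**defaults)
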