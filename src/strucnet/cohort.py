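"""Synthetic cohorts of streamline-count connectomes with planted group effects.

The generator emulates a three-group dementia study (Alzheimer's-like "AD",
subcortical-ischemic-vascular-dementia-like "SIVD", and normal controls "NC")
in which each subject contributes a symmetric 90x90 matrix of white-matter
streamline counts plus the nuisance covariates age, sex, and years of
education. A single modular "base" connectome plays the role of the healthy
population template; group pathology is planted as multiplicative
attenuation/inflation of count blocks between named node modules, and
between-subject variability is lognormal multiplicative noise on every
retained count.

Module labels ("frontal", "prefrontal", "temporal", "occipital",
"subcortical", "parietal") are generative block assignments, not real AAL
anatomy; they exist so planted effects can be addressed the way the study
describes its findings (e.g. "decreased temporal-occipital connections").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CovariateModel",
    "EffectProfile",
    "CohortSpec",
    "SubjectRecord",
    "GroundTruth",
    "MODULE_NAMES",
    "STUDY_COVARIATES",
    "identity_profile",
    "default_effect_profiles",
    "bc_reduction_profile",
    "edge_attenuation_profile",
    "make_base_template",
    "apply_effect",
    "sample_covariates",
    "generate_cohort",
    "manifest_frame",
    "connected_edge_subset",
]

MODULE_NAMES = (
    "frontal",
    "prefrontal",
    "temporal",
    "occipital",
    "subcortical",
    "parietal",
)

# Default fiber threshold of the ">3 streamlines" edge rule; kept here so the
# generator can guarantee that its *binary* template is connected.
FIBER_THRESHOLD = 3


@dataclass(frozen=True)
class CovariateModel:
    """Per-group covariate moments: age/education normal moments (years) and
    the fraction of female subjects."""

    age_mean: float
    age_sd: float
    education_mean: float
    education_sd: float
    female_fraction: float

    def validate(self) -> None:
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ValueError("female_fraction must be in [0, 1]")
        if self.age_sd < 0 or self.education_sd < 0:
            raise ValueError("covariate SDs must be nonnegative")


#: Group demographic moments of the emulated study (age and education in
#: years, mean +/- SD; sex ratios F/M 17/14, 9/10, 11/6).
STUDY_COVARIATES: Mapping[str, CovariateModel] = {
    "AD": CovariateModel(72.19, 8.90, 9.03, 6.11, 17 / 31),
    "SIVD": CovariateModel(79.10, 7.07, 10.37, 5.16, 9 / 19),
    "NC": CovariateModel(68.06, 8.33, 10.53, 3.39, 11 / 17),
}

Block = tuple[Sequence[int], Sequence[int], float]


@dataclass(frozen=True)
class EffectProfile:
    """Planted group pathology.

    ``attenuated_blocks`` / ``inflated_blocks`` are ``(nodes_a, nodes_b,
    factor)`` triples: every count linking a node in ``nodes_a`` with a node
    in ``nodes_b`` is multiplied by ``factor`` (<1 attenuates, >1 inflates).
    Overlapping blocks compose multiplicatively. ``nodal_bc_targets`` records
    which nodes the profile is expected to strip of betweenness centrality;
    it is bookkeeping for recovery experiments, not part of the generative
    model.

    ``node_swaps`` relabels node pairs (applied after block multiplication,
    before noise): swapping a hub with a node whose edges were zeroed moves
    the hub's connections wholesale, producing an exactly localized
    centrality knockout (the two graphs are isomorphic via the
    transposition, so all other nodes keep their centrality).
    """

    attenuated_blocks: tuple[Block, ...] = ()
    inflated_blocks: tuple[Block, ...] = ()
    nodal_bc_targets: tuple[int, ...] = ()
    node_swaps: tuple[tuple[int, int], ...] = ()

    def validate(self, n_nodes: int) -> None:
        for blocks, test, kind in (
            (self.attenuated_blocks, lambda f: 0 < f < 1, "attenuated"),
            (self.inflated_blocks, lambda f: f > 1, "inflated"),
        ):
            for a, b, factor in blocks:
                if not factor >= 0:
                    raise ValueError("block factors must be > 0")
                if kind == "attenuated" and not (0 <= factor < 1):
                    raise ValueError(
                        f"attenuated block factor {factor} must be in [0, 1)"
                    )
                if kind == "inflated" and not factor > 1:
                    raise ValueError(f"inflated block factor {factor} must be > 1")
                for nodes in (a, b):
                    idx = np.asarray(nodes, dtype=int)
                    if idx.size and (idx.min() < 0 or idx.max() >= n_nodes):
                        raise ValueError("block node index out of range")
        for v in self.nodal_bc_targets:
            if not 0 <= v < n_nodes:
                raise ValueError("nodal_bc_targets index out of range")
        seen: set[int] = set()
        for a, b in self.node_swaps:
            if not (0 <= a < n_nodes and 0 <= b < n_nodes) or a == b:
                raise ValueError("node_swaps must pair distinct in-range nodes")
            if a in seen or b in seen:
                raise ValueError("node_swaps must be disjoint transpositions")
            seen.update((a, b))

    def factor_matrix(self, n_nodes: int) -> np.ndarray:
        """Dense symmetric matrix of combined multiplicative factors."""
        self.validate(n_nodes)
        fmat = np.ones((n_nodes, n_nodes))
        for a, b, factor in (*self.attenuated_blocks, *self.inflated_blocks):
            ai = np.asarray(a, dtype=int)
            bi = np.asarray(b, dtype=int)
            mask = np.zeros((n_nodes, n_nodes), dtype=bool)
            mask[np.ix_(ai, bi)] = True
            mask[np.ix_(bi, ai)] = True
            fmat[mask] *= factor
        np.fill_diagonal(fmat, 1.0)
        return fmat


identity_profile = EffectProfile()


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters of one synthetic cohort.

    Defaults reproduce the emulated study's conditions: group sizes 31 AD /
    19 SIVD / 17 NC, 90 network nodes in six equal modules, and the emulated study's
    covariate moments. ``effect_profiles=None`` means "use the built-in AD
    and SIVD profiles" (see :func:`default_effect_profiles`); pass ``{}`` for
    an explicit all-null cohort.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"AD": 31, "SIVD": 19, "NC": 17}
    )
    n_nodes: int = 90
    n_modules: int = 6
    intra_module_edge_prob: float = 0.4
    inter_module_edge_prob: float = 0.015
    count_mean: float = 30.0
    count_dispersion: float = 2.0
    count_noise_sigma: float = 0.25
    effect_profiles: Mapping[str, EffectProfile] | None = None
    covariate_models: Mapping[str, CovariateModel] = field(
        default_factory=lambda: dict(STUDY_COVARIATES)
    )
    seed: int = 42

    def validate(self) -> None:
        if not self.n_per_group:
            raise ValueError("n_per_group is empty")
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs at least 2 subjects, got {n}")
        for p in (self.intra_module_edge_prob, self.inter_module_edge_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("edge probabilities must be in [0, 1]")
        if self.count_mean <= 0:
            raise ValueError("count_mean must be > 0")
        if self.count_dispersion <= 0:
            raise ValueError("count_dispersion must be > 0")
        if self.count_noise_sigma < 0:
            raise ValueError("count_noise_sigma must be >= 0")
        if self.n_nodes < 2 or self.n_modules < 1 or self.n_modules > self.n_nodes:
            raise ValueError("need 1 <= n_modules <= n_nodes and n_nodes >= 2")
        if self.effect_profiles is not None:
            for prof in self.effect_profiles.values():
                prof.validate(self.n_nodes)

    def module_names(self) -> tuple[str, ...]:
        if self.n_modules <= len(MODULE_NAMES):
            return MODULE_NAMES[: self.n_modules]
        return MODULE_NAMES + tuple(
            f"module{i}" for i in range(len(MODULE_NAMES), self.n_modules)
        )

    def module_nodes(self) -> dict[str, np.ndarray]:
        """Module name -> node-index array (near-even contiguous split)."""
        parts = np.array_split(np.arange(self.n_nodes), self.n_modules)
        return dict(zip(self.module_names(), parts))

    def node_labels(self) -> list[str]:
        labels = [""] * self.n_nodes
        for name, nodes in self.module_nodes().items():
            for k, v in enumerate(nodes):
                labels[int(v)] = f"{name}_{k + 1:02d}"
        return labels

    def resolved_profiles(self) -> dict[str, EffectProfile]:
        if self.effect_profiles is not None:
            profs = dict(self.effect_profiles)
        else:
            profs = default_effect_profiles(self)
        for g in self.n_per_group:
            profs.setdefault(g, identity_profile)
        return profs


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: identifier, group, covariates, streamline-count matrix."""

    subject_id: str
    group: str
    age: float
    sex: str  # "F" or "M"
    education: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = self.counts
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be square")
        if not np.array_equal(c, c.T):
            raise ValueError("counts must be symmetric")
        if np.any(np.diagonal(c) != 0):
            raise ValueError("counts diagonal must be zero")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: the shared base template, the per-group perturbed
    edges ``(i, j, combined factor)`` (upper triangle, base-present edges with
    factor != 1), and the per-group BC-target node sets."""

    base_template: np.ndarray
    perturbed_edges: dict[str, list[tuple[int, int, float]]]
    nodal_bc_targets: dict[str, tuple[int, ...]]


def default_effect_profiles(spec: CohortSpec) -> dict[str, EffectProfile]:
    """Built-in AD / SIVD pathology for the default module layout.

    AD: temporal and occipital blocks attenuated (including their mutual
    block), frontal-prefrontal block inflated. SIVD: every block among
    frontal, prefrontal, and subcortical attenuated. Modules missing from a
    custom spec are silently skipped (the profile degrades toward identity).
    """
    mods = spec.module_nodes()

    def blocks(pairs: list[tuple[str, str]], factor: float) -> tuple[Block, ...]:
        out: list[Block] = []
        for a, b in pairs:
            if a in mods and b in mods:
                out.append((tuple(map(int, mods[a])), tuple(map(int, mods[b])), factor))
        return tuple(out)

    def targets(names: list[str], per_module: int = 3) -> tuple[int, ...]:
        out: list[int] = []
        for name in names:
            if name in mods:
                out.extend(int(v) for v in mods[name][:per_module])
        return tuple(out)

    ad = EffectProfile(
        attenuated_blocks=blocks(
            [("temporal", "temporal"), ("occipital", "occipital"), ("temporal", "occipital")],
            0.5,
        ),
        inflated_blocks=blocks([("frontal", "prefrontal")], 1.5),
        nodal_bc_targets=targets(["temporal", "occipital"]),
    )
    sivd = EffectProfile(
        attenuated_blocks=blocks(
            [
                ("frontal", "frontal"),
                ("prefrontal", "prefrontal"),
                ("subcortical", "subcortical"),
                ("frontal", "prefrontal"),
                ("frontal", "subcortical"),
                ("prefrontal", "subcortical"),
            ],
            0.35,
        ),
        nodal_bc_targets=targets(["prefrontal", "subcortical"]),
    )
    return {"AD": ad, "SIVD": sivd}


def bc_reduction_profile(
    nodes: Sequence[int], factor: float, n_nodes: int
) -> EffectProfile:
    """Profile that strips the given nodes of centrality by attenuating every
    count incident to them by ``factor``.

    Edges between two target nodes receive ``factor**2`` (blocks compose).
    """
    everyone = tuple(range(n_nodes))
    blocks = tuple(((int(v),), everyone, factor) for v in nodes)
    return EffectProfile(
        attenuated_blocks=blocks, nodal_bc_targets=tuple(int(v) for v in nodes)
    )


def hub_knockout_profiles(
    base: np.ndarray, targets: Sequence[int]
) -> tuple[EffectProfile, EffectProfile]:
    """Design an exactly localized nodal-centrality knockout.

    For each target node a "spare" twin is chosen (the lowest-degree
    non-target nodes of ``base``'s binary form). Returns ``(reference_profile,
    knockout_profile)``:

    * the reference profile zeroes the spares' native edges (give it to every
      group, so the spares are inert everywhere);
    * the knockout profile additionally transposes each target with its
      spare, which moves the target's connections wholesale onto the spare.

    The two resulting graphs are isomorphic via the transpositions, so the
    population betweenness of every *other* node is identical between
    groups: the planted ground truth is exactly the targets (decreased; the
    spares increase correspondingly).
    """
    targets = [int(t) for t in targets]
    n = base.shape[0]
    degree = (base > FIBER_THRESHOLD).sum(axis=1)
    order = [int(v) for v in np.argsort(degree, kind="stable") if int(v) not in targets]
    spares = order[: len(targets)]
    if len(spares) < len(targets):
        raise ValueError("not enough non-target nodes to serve as spares")
    everyone = tuple(range(n))
    zero_blocks = tuple(((s,), everyone, 0.0) for s in spares)
    reference = EffectProfile(attenuated_blocks=zero_blocks)
    knockout = EffectProfile(
        attenuated_blocks=zero_blocks,
        node_swaps=tuple(zip(targets, spares)),
        nodal_bc_targets=tuple(targets),
    )
    return reference, knockout


def edge_attenuation_profile(
    edges: Sequence[tuple[int, int]], factor: float
) -> EffectProfile:
    """Profile attenuating an explicit edge list by a common factor."""
    blocks = tuple(((int(i),), (int(j),), factor) for i, j in edges)
    return EffectProfile(attenuated_blocks=blocks)


def connected_edge_subset(counts: np.ndarray, n_edges: int) -> list[tuple[int, int]]:
    """Deterministically pick ``n_edges`` present edges forming a connected
    subgraph (greedy frontier expansion from the highest-count node).

    Used to plant connected components for recovery experiments.
    """
    present = counts > 0
    start = int(np.argmax(present.sum(axis=1)))
    visited = {start}
    chosen: list[tuple[int, int]] = []
    frontier = [start]
    while len(chosen) < n_edges and frontier:
        u = frontier.pop(0)
        for v in np.flatnonzero(present[u]):
            v = int(v)
            edge = (min(u, v), max(u, v))
            if edge not in chosen:
                if v in visited and len(chosen) < n_edges:
                    # close a cycle inside the visited set only if both seen
                    continue
                chosen.append(edge)
                visited.add(v)
                frontier.append(v)
                if len(chosen) == n_edges:
                    break
    if len(chosen) < n_edges:
        raise ValueError(
            f"could not assemble {n_edges} connected edges (found {len(chosen)})"
        )
    return chosen


# ---------------------------------------------------------------------------
# generative operations
# ---------------------------------------------------------------------------


def _binary_connected(counts: np.ndarray, threshold: int = FIBER_THRESHOLD) -> bool:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    adj = counts > threshold
    n_comp, _ = connected_components(csr_matrix(adj), directed=False)
    return n_comp == 1


def make_base_template(
    spec: CohortSpec, rng: np.random.Generator, max_redraws: int = 20
) -> np.ndarray:
    """Draw the shared healthy-template count matrix.

    Edges are present with modular Bernoulli probabilities (intra-module >
    inter-module); present edges carry negative-binomial counts with mean
    ``count_mean`` and dispersion ``count_dispersion`` (variance m + m^2/k,
    the heavy-tailed regime typical of streamline counts). The template is
    redrawn until its binary form (counts > 3) is connected; a spec for which
    the redraw budget is exhausted is considered degenerate and raises.
    """
    spec.validate()
    n = spec.n_nodes
    module_of = np.empty(n, dtype=int)
    for m, nodes in enumerate(spec.module_nodes().values()):
        module_of[nodes] = m
    iu, ju = np.triu_indices(n, k=1)
    intra = module_of[iu] == module_of[ju]
    probs = np.where(intra, spec.intra_module_edge_prob, spec.inter_module_edge_prob)

    k = spec.count_dispersion
    p_nb = k / (k + spec.count_mean)
    for _ in range(max_redraws):
        present = rng.random(iu.size) < probs
        vals = np.zeros(iu.size, dtype=int)
        n_present = int(present.sum())
        if n_present:
            vals[present] = rng.negative_binomial(k, p_nb, size=n_present)
        counts = np.zeros((n, n), dtype=int)
        counts[iu, ju] = vals
        counts[ju, iu] = vals
        if _binary_connected(counts):
            return counts
    raise RuntimeError(
        "base template binary form stayed disconnected after "
        f"{max_redraws} redraws; spec is degenerate (edge probabilities too low?)"
    )


def apply_effect(
    base: np.ndarray,
    profile: EffectProfile,
    rng: np.random.Generator,
    noise_sigma: float = 0.0,
) -> np.ndarray:
    """Apply a planted effect plus per-subject noise to the base counts.

    Each upper-triangle count is multiplied by the profile's combined block
    factor and, when ``noise_sigma > 0``, by a lognormal deviate
    exp(N(0, sigma^2)); the product is rounded once to an integer and
    mirrored. Symmetry and the zero diagonal are preserved by construction.
    """
    n = base.shape[0]
    fmat = profile.factor_matrix(n)
    scaled = base.astype(float) * fmat
    if profile.node_swaps:
        perm = np.arange(n)
        for a, b in profile.node_swaps:
            perm[a], perm[b] = perm[b], perm[a]
        scaled = scaled[np.ix_(perm, perm)]
    iu, ju = np.triu_indices(n, k=1)
    vals = scaled[iu, ju]
    if noise_sigma > 0:
        noise = np.exp(rng.normal(0.0, noise_sigma, size=vals.size))
        vals = vals * noise
    vals = np.rint(vals).astype(int)
    np.maximum(vals, 0, out=vals)
    out = np.zeros_like(base)
    out[iu, ju] = vals
    out[ju, iu] = vals
    return out


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float,
    hi: float = math.inf,
) -> float:
    if sd == 0:
        return float(min(max(mean, lo), hi))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    raise RuntimeError("truncated-normal rejection sampling failed (bounds too tight)")


def sample_covariates(
    group: str, spec: CohortSpec, rng: np.random.Generator
) -> tuple[float, str, float]:
    """Draw (age, sex, education) for one subject of ``group``.

    Age is normal at the group's published demographic moments truncated to [40, 100] years;
    education is truncated at 0; sex is Bernoulli at the group's female
    fraction. Groups without a covariate model fall back to the NC model.
    """
    model = spec.covariate_models.get(group)
    if model is None:
        if group in spec.n_per_group:
            model = STUDY_COVARIATES["NC"]
        else:
            raise KeyError(f"unknown group {group!r}")
    model.validate()
    age = _truncated_normal(rng, model.age_mean, model.age_sd, 40.0, 100.0)
    education = _truncated_normal(rng, model.education_mean, model.education_sd, 0.0)
    sex = "F" if rng.random() < model.female_fraction else "M"
    return age, sex, education


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], GroundTruth]:
    """Generate the full cohort: subjects (grouped, in manifest order) plus
    the ground truth of every planted perturbation.

    Deterministic: the spec's seed drives a SeedSequence from which the
    template, covariate, and per-subject noise streams are spawned, so the
    same spec yields bit-identical output.
    """
    spec.validate()
    n_subjects = int(sum(spec.n_per_group.values()))
    ss = np.random.SeedSequence(spec.seed)
    template_ss, cov_ss, *subj_ss = ss.spawn(2 + n_subjects)
    base = make_base_template(spec, np.random.default_rng(template_ss))
    profiles = spec.resolved_profiles()

    iu, ju = np.triu_indices(spec.n_nodes, k=1)
    perturbed: dict[str, list[tuple[int, int, float]]] = {}
    targets: dict[str, tuple[int, ...]] = {}
    for g in spec.n_per_group:
        prof = profiles[g]
        fmat = prof.factor_matrix(spec.n_nodes)
        sel = (base[iu, ju] > 0) & (fmat[iu, ju] != 1.0)
        perturbed[g] = [
            (int(i), int(j), float(f))
            for i, j, f in zip(iu[sel], ju[sel], fmat[iu, ju][sel])
        ]
        targets[g] = prof.nodal_bc_targets

    cov_rng = np.random.default_rng(cov_ss)
    subjects: list[SubjectRecord] = []
    idx = 0
    for g, n in spec.n_per_group.items():
        prof = profiles[g]
        for k in range(n):
            age, sex, education = sample_covariates(g, spec, cov_rng)
            counts = apply_effect(
                base, prof, np.random.default_rng(subj_ss[idx]), spec.count_noise_sigma
            )
            subjects.append(
                SubjectRecord(
                    subject_id=f"{g}_{k + 1:02d}",
                    group=g,
                    age=age,
                    sex=sex,
                    education=education,
                    counts=counts,
                )
            )
            idx += 1
    return subjects, GroundTruth(base, perturbed, targets)


def spec_template(spec: CohortSpec) -> np.ndarray:
    """The exact base template :func:`generate_cohort` will draw for ``spec``
    (same seed substream), without generating any subjects.

    Useful for designing planted effects against the template that the full
    cohort will actually share.
    """
    spec.validate()
    child = np.random.SeedSequence(spec.seed).spawn(1)[0]
    return make_base_template(spec, np.random.default_rng(child))


def manifest_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Subject manifest (id, group, age, sex, education) as a DataFrame."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "group": [s.group for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "education": [s.education for s in subjects],
        }
    )
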