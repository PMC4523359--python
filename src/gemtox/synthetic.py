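"""Synthetic OTU tables along a contamination gradient, with known truth.

The generator emulates the statistical structure the models assume: ~22
sites of which ~10 are uncontaminated (covariate exactly 0), a covariate
range of 0-22,000 mg/kg with tied positive values (to exercise jittering),
a few hundred OTUs with strongly skewed (GEM-type stick-breaking) baseline
abundances, and three planted response groups — OTUs whose relative
abundance increases, decreases, or is unaffected as the covariate grows.

Planted responses are logistic in the covariate.  The logistic centre is
drawn once per response *group* (uniformly over the covariate range): with a
shared centre the per-OTU proportion curves remain provably monotone after
per-site renormalization, so planted labels are unambiguous ground truth.
Counts are multinomial draws at per-site depths; OTU identifiers carry a
synthetic one-genus-per-OTU label (``genus_k``) so the reference-list
comparison path can be exercised without real taxonomy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from gemtox.gem import sample_stick_fractions, stick_break
from gemtox.tables import CovariateVector, OTUCountTable

__all__ = [
    "SyntheticDesign",
    "GroundTruth",
    "benchmark_design",
    "generate_covariates",
    "generate_true_compositions",
    "sample_counts",
    "generate_reference_list",
    "simulate_dataset",
    "write_dataset",
]

_NORM_TOL = 1e-10

LABELS = ("increasing", "decreasing", "unaffected")


@dataclass(frozen=True)
class SyntheticDesign:
    """Study design for one synthetic data set.

    Defaults emulate the field data the models were built for: 22 sites, 10
    of them uncontaminated, covariate up to 22,000 mg/kg, 450 candidate OTUs
    with GEM(concentration=20) baseline skew, sequencing depths 2,000-10,000
    per site, and a 20/20/60% split into increasing / decreasing /
    unaffected response groups.
    """

    n_sites: int = 22
    n_baseline: int = 10
    max_covariate: float = 22_000.0
    n_otus: int = 450
    group_fractions: tuple[float, float, float] = (0.2, 0.2, 0.6)
    effect_scale: float = 2.0
    concentration: float = 20.0
    depth_range: tuple[int, int] = (2_000, 10_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1 or self.n_otus < 1:
            raise ValueError("n_sites and n_otus must be positive")
        if self.n_baseline < 0 or self.n_baseline > self.n_sites:
            raise ValueError("n_baseline must lie in [0, n_sites]")
        if self.max_covariate <= 0 or self.concentration <= 0:
            raise ValueError("max_covariate and concentration must be positive")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be nonnegative")
        if abs(sum(self.group_fractions) - 1.0) > 1e-9:
            raise ValueError("group_fractions must sum to 1")
        if any(f < 0 for f in self.group_fractions):
            raise ValueError("group_fractions must be nonnegative")
        lo, hi = self.depth_range
        if lo < 1 or lo > hi:
            raise ValueError("depth_range must satisfy 1 <= min <= max")


def benchmark_design(seed: int = 0) -> SyntheticDesign:
    """Strong-effect benchmark: deep sequencing (>= 5,000 reads/site) and a
    steep planted response, used for end-to-end recovery checks."""
    return SyntheticDesign(effect_scale=3.0, depth_range=(5_000, 10_000), seed=seed)


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth behind a synthetic table.

    ``true_compositions`` is (n_sites, n_otus) with rows summing to one;
    ``group_labels`` gives each OTU's planted response; ``reference_list``
    is the clean set of "known degrader" genera (exactly the genera of the
    increasing group).
    """

    true_compositions: np.ndarray
    group_labels: tuple[str, ...]
    otu_ids: tuple[str, ...]
    genera: tuple[str, ...]
    reference_list: frozenset[str]
    baseline_weights: np.ndarray
    response_centres: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        comps = np.asarray(self.true_compositions, dtype=float)
        if not np.allclose(comps.sum(axis=1), 1.0, atol=_NORM_TOL, rtol=0.0):
            raise ValueError("true compositions must sum to 1 within 1e-10")
        if set(self.group_labels) - set(LABELS):
            raise ValueError(f"labels must be among {LABELS}")
        if not (len(self.group_labels) == len(self.otu_ids) == len(self.genera)
                == comps.shape[1]):
            raise ValueError("per-OTU fields must all have length n_otus")
        object.__setattr__(self, "true_compositions", comps)


def generate_covariates(design: SyntheticDesign) -> CovariateVector:
    """Per-site covariates: exactly ``n_baseline`` zeros; positive values
    uniform on (0, max_covariate] with the largest pinned at the maximum and
    ceil(n_sites/4) sites sharing duplicated (tied) positive values."""
    rng = np.random.default_rng(design.seed)
    n_pos = design.n_sites - design.n_baseline
    values = np.zeros(design.n_sites)
    if n_pos > 0:
        n_dup = min(int(np.ceil(design.n_sites / 4)), n_pos - 1) if n_pos >= 2 else 0
        base = rng.uniform(0.0, design.max_covariate, size=n_pos - n_dup)
        base[base == 0.0] = design.max_covariate / 2.0  # measure-zero guard
        base = np.sort(base)
        base[-1] = design.max_covariate
        dups = rng.choice(base, size=n_dup, replace=True) if n_dup else np.empty(0)
        values[design.n_baseline:] = np.concatenate([base, dups])
    site_ids = tuple(f"site_{i + 1:02d}" for i in range(design.n_sites))
    return CovariateVector(raw=values, site_ids=site_ids)


def _logistic(x: np.ndarray, centre: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(x - centre) / width))


def _response(x: np.ndarray, centre: float, width: float,
              max_covariate: float) -> np.ndarray:
    """Logistic response rescaled to run exactly 0 -> 1 over [0, max].

    The affine normalization keeps the curve monotone while pinning the
    multiplier to 1 at covariate zero, so the planted baseline composition
    equals the GEM draw exactly.
    """
    s0 = _logistic(np.array([0.0]), centre, width)[0]
    s1 = _logistic(np.array([max_covariate]), centre, width)[0]
    return (_logistic(x, centre, width) - s0) / (s1 - s0)


def _stratified_labels(w: np.ndarray, fractions: tuple[float, float, float],
                       rng: np.random.Generator) -> np.ndarray:
    """Assign response groups stratified by abundance rank.

    OTUs are walked in decreasing-weight order in blocks of 5; each block
    receives group labels in the design proportions (largest-remainder
    quota), shuffled within the block.  Every response group then spans the
    whole abundance spectrum and holds a stable share of community mass,
    instead of the planted signal hinging on whether a dominant OTU happens
    to draw a signal label.
    """
    n = w.size
    order = np.argsort(-w, kind="stable")
    labels = np.empty(n, dtype=object)
    assigned = np.zeros(3)
    done = 0
    for start in range(0, n, 5):
        size = min(5, n - start)
        done += size
        quota = np.floor(done * np.asarray(fractions) - assigned).astype(int)
        quota = np.maximum(quota, 0)
        while quota.sum() < size:  # largest remainder tops up
            frac_part = done * np.asarray(fractions) - assigned - quota
            quota[np.argmax(frac_part)] += 1
        while quota.sum() > size:
            quota[np.argmax(quota)] -= 1
        block = sum(([LABELS[g]] * quota[g] for g in range(3)), [])
        rng.shuffle(block)
        labels[order[start:start + size]] = block
        assigned += quota
    return labels


def generate_true_compositions(design: SyntheticDesign,
                               covariates: CovariateVector) -> GroundTruth:
    """Plant smooth monotone responses on GEM-type baseline weights.

    Baseline relative weights come from a truncated GEM(concentration)
    stick-breaking draw (renormalized over the n_otus kept sticks).  Each
    OTU's weight is multiplied by exp(+-effect_scale * sigmoid) — rising for
    the increasing group, falling for the decreasing group, constant for the
    unaffected group — then renormalized per site.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    x = covariates.raw
    if x.size != design.n_sites:
        raise ValueError("covariates do not match the design")

    w = stick_break(sample_stick_fractions(design.concentration, design.n_otus, rng))
    w = w[:-1] / w[:-1].sum()  # drop and renormalize away the tail

    n = design.n_otus
    labels = _stratified_labels(w, design.group_fractions, rng)

    width = design.max_covariate / 6.0
    centres = {"increasing": float(rng.uniform(0.0, design.max_covariate)),
               "decreasing": float(rng.uniform(0.0, design.max_covariate))}
    mult = np.ones((design.n_sites, n))
    if design.effect_scale > 0:
        sig_inc = _response(x, centres["increasing"], width, design.max_covariate)
        sig_dec = _response(x, centres["decreasing"], width, design.max_covariate)
        mult[:, labels == "increasing"] = np.exp(
            design.effect_scale * sig_inc)[:, None]
        mult[:, labels == "decreasing"] = np.exp(
            -design.effect_scale * sig_dec)[:, None]
    comps = w[None, :] * mult
    comps /= comps.sum(axis=1, keepdims=True)

    otu_ids = tuple(f"otu_{k:04d}" for k in range(n))
    genera = tuple(f"genus_{k}" for k in range(n))
    reference = frozenset(g for g, lab in zip(genera, labels) if lab == "increasing")
    return GroundTruth(
        true_compositions=comps,
        group_labels=tuple(labels),
        otu_ids=otu_ids,
        genera=genera,
        reference_list=reference,
        baseline_weights=w,
        response_centres={**centres, "width": width,
                          "effect_scale": design.effect_scale},
    )


def sample_counts(truth: GroundTruth, covariates: CovariateVector,
                  design: SyntheticDesign) -> OTUCountTable:
    """Multinomial counts per site at a depth uniform over ``depth_range``."""
    comps = truth.true_compositions
    if not np.allclose(comps.sum(axis=1), 1.0, atol=_NORM_TOL, rtol=0.0):
        raise ValueError("compositions must be normalized")
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 2]))
    lo, hi = design.depth_range
    depths = rng.integers(lo, hi + 1, size=covariates.raw.size)
    counts = np.empty((comps.shape[1], covariates.raw.size), dtype=np.int64)
    for i, depth in enumerate(depths):
        counts[:, i] = rng.multinomial(depth, comps[i] / comps[i].sum())
    return OTUCountTable(counts=counts, otu_ids=truth.otu_ids,
                         site_ids=covariates.site_ids, genera=truth.genera)


def generate_reference_list(truth: GroundTruth, misannotation_rate: float = 0.0,
                            seed: int = 0) -> set[str]:
    """Imperfect external 'known degrader' genus list.

    Starts from the genera of the increasing group; each genus in the study
    flips its membership (in or out of the list) independently with
    probability ``misannotation_rate``.  Rate 0 returns the clean list;
    rate 1 returns its exact complement.
    """
    if not 0.0 <= misannotation_rate <= 1.0:
        raise ValueError("misannotation_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    listed = set(truth.reference_list)
    out = set()
    for genus in truth.genera:
        member = genus in listed
        if rng.random() < misannotation_rate:
            member = not member
        if member:
            out.add(genus)
    return out


def simulate_dataset(design: SyntheticDesign
                     ) -> tuple[OTUCountTable, CovariateVector, GroundTruth]:
    """Covariates, planted truth and a sampled count table, in one call."""
    cov = generate_covariates(design)
    truth = generate_true_compositions(design, cov)
    table = sample_counts(truth, cov, design)
    return table, cov, truth


def write_dataset(table: OTUCountTable, cov: CovariateVector, truth: GroundTruth,
                  outdir: str | Path, misannotation_rate: float = 0.0,
                  seed: int = 0) -> dict[str, Path]:
    """Write table, metadata, reference list and a ground-truth JSON sidecar."""
    from gemtox.tables import write_metadata, write_otu_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": outdir / "otu_table.tsv",
        "metadata": outdir / "metadata.tsv",
        "reference": outdir / "reference_genera.txt",
        "truth": outdir / "ground_truth.json",
    }
    write_otu_table(table, paths["table"])
    write_metadata(cov, paths["metadata"])
    reference = generate_reference_list(truth, misannotation_rate, seed)
    paths["reference"].write_text("\n".join(sorted(reference)) + "\n")
    sidecar = {
        "group_labels": list(truth.group_labels),
        "otu_ids": list(truth.otu_ids),
        "genera": list(truth.genera),
        "reference_list": sorted(truth.reference_list),
        "baseline_weights": np.asarray(truth.baseline_weights).tolist(),
        "true_compositions": np.asarray(truth.true_compositions).tolist(),
        "response_centres": truth.response_centres,
    }
    paths["truth"].write_text(json.dumps(sidecar))
    return paths
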