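"""Synthetic datasets with known planted structure.

Every downstream stage of the pipeline (scoring, differential expression,
clustering, archetype classification, seed scanning, qPCR quantification)
is testable against these generators because each one returns its ground
truth alongside the data.

Two study designs are emulated:

* a biopsy cohort (controls + dystrophic samples) in which a latent
  per-sample fibrosis level drives both three fibrotic marker genes and a
  planted set of positively coupled "fibromiRs" / negatively coupled
  "myomiRs" in negative-binomially distributed miRNA counts;
* a 2x2 progenitor-by-treatment design (FAP/MP x +/-TGFb1) with four
  planted miRNA profile archetypes plus background.

All distributional laws here are stand-ins chosen for plausibility — the
emulated study reports no generative parameters — so recovery results on
these data demonstrate correctness of the machinery, not performance on
real biopsies.  All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import seeds as _seeds
from .clustering import CONDITIONS
from .qpcr import CT_COLUMNS

__all__ = [
    "FibrosisLaw",
    "CohortParams",
    "DesignParams",
    "CohortTruth",
    "DesignTruth",
    "generate_cohort",
    "generate_design",
    "generate_ct_table",
    "generate_utr_with_sites",
]


@dataclass(frozen=True)
class FibrosisLaw:
    """Latent fibrosis distribution: controls low; cases split Low/High.

    The Low fraction of cases is planted with fixed proportions (rounded),
    reproducing the emulated cohort's 3-Low / 5-High structure exactly at
    n_dmd = 8 rather than on average.
    """

    control_range: tuple[float, float] = (0.0, 0.2)
    low_range: tuple[float, float] = (0.0, 0.2)
    high_range: tuple[float, float] = (0.4, 1.0)
    dmd_low_fraction: float = 3 / 8


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the biopsy-cohort generator.

    ``beta`` is the planted coupling (log2 expression units per unit latent
    fibrosis) applied with sign +1 to fibromiRs and -1 to myomiRs;
    ``dispersion`` is the NB dispersion alpha in var = mu + alpha*mu^2;
    ``depth`` the expected library size per sample.

    The three fibrotic marker genes respond to latent fibrosis through a
    saturating (Hill-type) activation: log expression is
    ``marker_gain * sigmoid(marker_steepness * (f - marker_midpoint))``
    plus lognormal noise.  The switch-like response places the fibrotic
    score reliably on either side of the 0.25 stratification threshold for
    samples below/above the latent Low/High bands, whatever the cohort
    maximum happens to be.
    """

    n_control: int = 3
    n_dmd: int = 8
    n_mirnas: int = 600
    n_fibromirs: int = 25
    n_myomirs: int = 8
    beta: float = 2.0
    dispersion: float = 0.05
    depth: float = 1e5
    fibrosis_law: FibrosisLaw = field(default_factory=FibrosisLaw)
    marker_gain: float = 3.0
    marker_midpoint: float = 0.3
    marker_steepness: float = 20.0
    marker_noise_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_fibromirs + self.n_myomirs > self.n_mirnas:
            raise ValueError("planted miRNAs exceed n_mirnas")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if min(self.n_control, self.n_dmd, self.n_mirnas) < 1:
            raise ValueError("sample and miRNA counts must be positive")


@dataclass(frozen=True)
class DesignParams:
    """Parameters of the 2x2 FAP/MP x +/-TGFb1 design generator.

    ``archetype_counts`` plants miRNAs per archetype: C1 (MP-enriched, down
    with TGFb1), C2 (MP-enriched, flat), C3 (FAP-enriched, down), C4
    (FAP-enriched, up) and background (flat everywhere).
    ``enrichment_lfc`` is the planted log2 FAP-vs-MP separation,
    ``response_lfc`` the planted log2 TGFb1 response in the enriched cell.
    """

    n_replicates: int = 3
    archetype_counts: dict = field(
        default_factory=lambda: {"C1": 15, "C2": 15, "C3": 15, "C4": 15, "background": 140}
    )
    enrichment_lfc: float = 4.0
    response_lfc: float = 2.0
    dispersion: float = 0.02
    depth: float = 1e5
    seed: int = 0

    def validate(self) -> None:
        known = {"C1", "C2", "C3", "C4", "background"}
        if set(self.archetype_counts) - known:
            raise ValueError(f"unknown archetype keys: {set(self.archetype_counts) - known}")
        if any(v < 0 for v in self.archetype_counts.values()):
            raise ValueError("archetype counts must be >= 0")
        if sum(self.archetype_counts.values()) < 1:
            raise ValueError("need at least one miRNA")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.dispersion < 0 or self.depth <= 0:
            raise ValueError("dispersion must be >= 0 and depth positive")


@dataclass
class CohortTruth:
    """Ground truth of a generated cohort."""

    mirna_class: pd.Series  # fibromiR | myomiR | background
    latent_fibrosis: pd.Series  # per sample, >= 0
    group: pd.Series  # control | DMD
    planted_stratum: pd.Series  # Low | High by latent band


@dataclass
class DesignTruth:
    """Ground truth of a generated 2x2 design."""

    mirna_class: pd.Series  # C1..C4 | background
    condition: pd.Series  # per sample


def _nb_draws(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, var = mu + alpha mu^2) counts; Poisson when alpha == 0."""
    mu = np.asarray(mu, dtype=float)
    if alpha < 1e-12:
        return rng.poisson(mu)
    size = 1.0 / alpha
    return rng.negative_binomial(size, size / (size + mu))


def generate_cohort(params: CohortParams) -> tuple[pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Simulate a biopsy cohort: counts, marker panel and ground truth.

    Counts for miRNA i in sample s are NB with
    log2 mean = baseline_i + beta * f_s * c_i, where c_i is +1 for planted
    fibromiRs, -1 for myomiRs and 0 for background, and f_s is the latent
    fibrosis level.  Marker expression for each of COL1A1 / FN1 / ACTA2 is
    exp(marker_gain * sigmoid(f_s)) with lognormal noise (see
    :class:`CohortParams`).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    law = params.fibrosis_law

    sample_ids = [f"CT{i + 1}" for i in range(params.n_control)] + [
        f"DMD{i + 1}" for i in range(params.n_dmd)
    ]
    group = pd.Series(
        ["control"] * params.n_control + ["DMD"] * params.n_dmd, index=sample_ids, name="group"
    )

    # latent fibrosis: controls low; a fixed-proportion Low subset of cases
    n_low = int(round(law.dmd_low_fraction * params.n_dmd))
    f_control = rng.uniform(*law.control_range, size=params.n_control)
    f_low = rng.uniform(*law.low_range, size=n_low)
    f_high = rng.uniform(*law.high_range, size=params.n_dmd - n_low)
    strata_dmd = np.array(["Low"] * n_low + ["High"] * (params.n_dmd - n_low))
    order = rng.permutation(params.n_dmd)
    f_dmd = np.concatenate([f_low, f_high])[order]
    strata_dmd = strata_dmd[order]
    f = np.concatenate([f_control, f_dmd])
    latent = pd.Series(f, index=sample_ids, name="latent_fibrosis")
    planted_stratum = pd.Series(
        np.concatenate([np.repeat("Low", params.n_control), strata_dmd]),
        index=sample_ids,
        name="planted_stratum",
    )

    mirna_ids = [f"miR-{i + 1:04d}" for i in range(params.n_mirnas)]
    coupling = np.zeros(params.n_mirnas)
    coupling[: params.n_fibromirs] = 1.0
    coupling[params.n_fibromirs : params.n_fibromirs + params.n_myomirs] = -1.0
    classes = np.where(coupling > 0, "fibromiR", np.where(coupling < 0, "myomiR", "background"))

    # baseline relative abundances: heavy-tailed, as in real small-RNA libraries
    w = rng.lognormal(mean=0.0, sigma=1.5, size=params.n_mirnas)
    w /= w.sum()
    mu = params.depth * w[:, None] * 2.0 ** (params.beta * f[None, :] * coupling[:, None])
    counts = pd.DataFrame(
        _nb_draws(rng, mu, params.dispersion), index=mirna_ids, columns=sample_ids
    )

    noise = rng.normal(0.0, params.marker_noise_sd, size=(len(sample_ids), 3))
    activation = 1.0 / (1.0 + np.exp(-params.marker_steepness * (f - params.marker_midpoint)))
    markers = pd.DataFrame(
        np.exp(params.marker_gain * activation[:, None] + noise),
        index=sample_ids,
        columns=["COL1A1", "FN1", "ACTA2"],
    )

    truth = CohortTruth(
        mirna_class=pd.Series(classes, index=mirna_ids, name="class"),
        latent_fibrosis=latent,
        group=group,
        planted_stratum=planted_stratum,
    )
    return counts, markers, truth


_ARCHETYPE_ORDER = ("C1", "C2", "C3", "C4", "background")


def generate_design(params: DesignParams) -> tuple[pd.DataFrame, DesignTruth]:
    """Simulate the 2x2 FAP/MP x +/-TGFb1 design with planted archetypes."""
    params.validate()
    rng = np.random.default_rng(params.seed)

    classes: list[str] = []
    for c in _ARCHETYPE_ORDER:
        classes += [c] * params.archetype_counts.get(c, 0)
    n = len(classes)
    mirna_ids = [f"miR-{i + 1:04d}" for i in range(n)]

    sample_ids, condition = [], []
    for cond in CONDITIONS:
        for r in range(params.n_replicates):
            sample_ids.append(f"{cond}-{r + 1}")
            condition.append(cond)
    condition = pd.Series(condition, index=sample_ids, name="condition")

    w = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    w /= w.sum()
    base = params.depth * w

    e2 = params.enrichment_lfc / 2.0
    r_lfc = params.response_lfc
    # per-condition log2 offsets, columns in CONDITIONS order
    offsets = {
        "C1": (-e2, -e2, +e2, +e2 - r_lfc),
        "C2": (-e2, -e2, +e2, +e2),
        "C3": (+e2, +e2 - r_lfc, -e2, -e2),
        "C4": (+e2, +e2 + r_lfc, -e2, -e2),
        "background": (0.0, 0.0, 0.0, 0.0),
    }
    log2_off = np.array([offsets[c] for c in classes])  # n x 4
    cond_index = {c: j for j, c in enumerate(CONDITIONS)}
    mu = base[:, None] * 2.0 ** log2_off[:, [cond_index[c] for c in condition]]

    counts = pd.DataFrame(
        _nb_draws(rng, mu, params.dispersion), index=mirna_ids, columns=sample_ids
    )
    truth = DesignTruth(
        mirna_class=pd.Series(classes, index=mirna_ids, name="class"),
        condition=condition,
    )
    return counts, truth


def generate_ct_table(
    n_samples: int,
    true_log2_fold: float,
    noise_sd: float,
    seed: int = 0,
    target_gene: str = "COL1A1",
    reference_gene: str = "TBP",
    baseline_dct: float = 2.0,
    ct_ref: float = 20.0,
) -> pd.DataFrame:
    """Simulate a two-arm qPCR Ct table (n_samples replicates per arm).

    Ct_target = Ct_ref + baseline_dct - true_log2_fold * 1(treated)
                + Normal(0, noise_sd)

    so the comparative-CT fold change of treated over control inverts to
    2**true_log2_fold exactly when noise_sd == 0.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for cond, shift in (("control", 0.0), ("treated", true_log2_fold)):
        eps = rng.normal(0.0, noise_sd, size=n_samples)
        for i in range(n_samples):
            rows.append(
                {
                    "sample": f"{cond}-{i + 1}",
                    "condition": cond,
                    "target_gene": target_gene,
                    "ct_target": ct_ref + baseline_dct - shift + eps[i],
                    "reference_gene": reference_gene,
                    "ct_ref": ct_ref,
                    "replicate": i + 1,
                }
            )
    return pd.DataFrame(rows, columns=CT_COLUMNS + ["replicate"])


def generate_utr_with_sites(
    utr_length: int,
    mirna_seq: str,
    planted: list[tuple[int, str]],
    seed: int = 0,
    utr_id: str = "utr",
    max_iter: int = 500,
) -> tuple[str, pd.DataFrame]:
    """A random UTR carrying exactly the requested seed sites.

    ``planted`` is a list of (1-based start, site type); sites must fit and
    must not overlap.  Background positions are uniform over A/C/G/T and
    re-sampled (rejection) wherever they would create an accidental site or
    alter a planted site's class, so a scan reports exactly the planted
    sites.

    Returns the sequence (DNA alphabet) and a truth table with columns
    ``start``, ``end``, ``site_type``.
    """
    rng = np.random.default_rng(seed)
    spans: list[tuple[int, int, str]] = []
    for start, site_type in planted:
        pat = _seeds.site_sequence(mirna_seq, site_type)
        end = start + len(pat) - 1
        if start < 1 or end > utr_length:
            raise ValueError(f"site {site_type} at {start} outside UTR of length {utr_length}")
        spans.append((start, end, site_type))
    spans.sort()
    for (s1, e1, _), (s2, e2, _) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise ValueError("planted sites overlap")

    planted_positions: set[int] = set()
    bases = list(rng.choice(list("ACGT"), size=utr_length))
    for start, end, site_type in spans:
        pat = _seeds.site_sequence(mirna_seq, site_type)
        bases[start - 1 : end] = list(pat)
        planted_positions.update(range(start - 1, end))

    want = {(s, t) for s, _, t in spans}
    for _ in range(max_iter):
        seq = "".join(bases)
        found = {(site.start, site.site_type) for site in _seeds.seed_sites(mirna_seq, seq, utr_id)}
        if found == want:
            truth = pd.DataFrame(
                [
                    {"start": s, "end": e, "site_type": t}
                    for s, e, t in spans
                ]
            )
            return seq, truth
        # re-sample the background positions of every unexpected site
        for start, site_type in found - want:
            pat_len = len(_seeds.site_sequence(mirna_seq, site_type))
            for pos in range(start - 1, start - 1 + pat_len):
                if pos not in planted_positions:
                    bases[pos] = rng.choice(list("ACGT"))
        # a planted site can only go missing if a flanking base upgraded it;
        # the unexpected stronger site overlaps it and is re-sampled above
    raise RuntimeError("could not place sites without accidental matches")
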