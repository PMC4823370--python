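"""Seeded generator of a synthetic three-line labeling study.

Emulates the measurement structure of a serum-deprivation SIRM experiment on
an untransfected motor-neuronal line (NSC-34) and two SOD1 transfectants
(WT-NSC, G93A-NSC) cultured with [U-13C6]glucose (25 mM) or
[U-13C5]glutamine (1 mM): media concentration tables read out by 1H NMR,
13C-satellite integrals, raw GC-MS isotopologue intensities with the full
natural-abundance background of TBDMS-derivatized fragments, and a
profiling intensity table with internal-standard and protein columns.

Every configured truth is annotated with the reported quantity it encodes;
group contrasts (for example the +46 % serum-free lactate-release difference
between the mutant and wild-type transfectant lines) are exact in the
noise-free limit, and measurement noise is multiplicative mean-one
lognormal, so pipeline estimates recover the truths without bias.

True MIDs for the labeling tables are two-component mixtures — an unlabeled
pool plus a uniformly tracer-labeled pool whose positions are 13C with the
tracer purity — scaled so the atom-level fractional enrichment equals the
configured truth exactly.  The mechanistic label-propagation model
(:mod:`sirmkit.tracer`) remains the source of isotopologue *patterns*; it is
not flux-fitted to pool enrichments, which would amount to full 13C-MFA.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .isotopes import correction_matrices, load_fragment_library
from .nmr import NATURAL_13C
from .profiling import STUDY_LINES
from .tracer import PathwayConfig

__all__ = [
    "LineTruth",
    "StudyConfig",
    "default_study_config",
    "generate_media_dataset",
    "generate_tracer_dataset",
    "generate_pool_dataset",
]


@dataclass(frozen=True)
class LineTruth:
    """True values for (NSC-34, WT-NSC, G93A-NSC) plus a provenance note."""

    values: tuple[float, float, float]
    note: str

    def for_line(self, line: str) -> float:
        return self.values[STUDY_LINES.index(line)]


@dataclass
class StudyConfig:
    """All true parameters and noise settings of the synthetic study."""

    # media exchange truths, umol per mg protein over the 22 h window
    exchange: dict[str, LineTruth]
    fresh_medium_mM: dict[str, float]
    # NMR tracer-source fractions per tracer -> metabolite -> lines
    source_fraction: dict[str, dict[str, LineTruth]]
    # GC-MS atom-level 13C enrichment truths per tracer -> metabolite -> lines
    enrichment: dict[str, dict[str, LineTruth]]
    # pool sizes as percent of the NSC-34 line
    pool_percent: dict[str, LineTruth]
    # mechanistic pathway settings per line (for simulate_experiment)
    pathway: dict[str, PathwayConfig]
    n_media: int = 4
    n_media_lactate: int = 8
    n_mid: int = 5
    n_pool: int = 6
    cv_intensity: float = 0.05
    cv_protein: float = 0.10
    cv_is: float = 0.20  # injected internal-standard variation, removed by normalization
    volume_ml: float = 2.0
    protein_mg_mean: float = 0.2
    tracer_glc_mM: float = 25.0
    tracer_gln_mM: float = 1.0
    tracer_purity: float = 0.99
    seed: int = 0

    def validate(self) -> None:
        for name in ("cv_intensity", "cv_protein", "cv_is"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_media", "n_media_lactate", "n_mid", "n_pool"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if not 0 < self.tracer_purity <= 1:
            raise ValueError("tracer purity must be in (0, 1]")
        for tracer, mets in self.enrichment.items():
            for met, truth in mets.items():
                for v in truth.values:
                    if not 0 <= v <= self.tracer_purity:
                        raise ValueError(
                            f"enrichment truth {tracer}/{met}={v} not attainable "
                            f"at purity {self.tracer_purity}"
                        )


def default_study_config(seed: int = 0) -> StudyConfig:
    """Study conditions with truths equal to the reported group values.

    Absolute media baselines and pool abundances are arbitrary units chosen
    at physiological plausibility; all *contrasts* (percent differences,
    source fractions, enrichments, fold-changes) are the reported values.
    """
    L = LineTruth
    exchange = {
        "lactate": L((10.0, 17.9, 26.134),
                     "reported serum-free lactate release: WT +79% and G93A +161% vs "
                     "NSC-34, G93A +46% vs WT (n=8); NSC-34 baseline arbitrary"),
        "glucose": L((-30.0, -35.0, -41.1),
                     "reported glucose consumption: G93A +37% vs NSC-34, WT intermediate"),
        "alanine": L((1.0, 2.97, 6.207),
                     "reported alanine release: WT +197% vs NSC-34, G93A +109% vs WT"),
        "formate": L((0.5, 1.185, 1.529),
                     "reported formate release: WT +137% vs NSC-34, G93A +29% vs WT"),
        "glutamate": L((2.0, 0.92, 1.297),
                       "reported glutamate release: WT -54% and G93A -35% vs NSC-34, "
                       "G93A +41% vs WT"),
        "glutamine": L((-4.0, -4.0, -4.0),
                       "glutamine consumption not significantly different between "
                       "lines; magnitude bounded by the 1 mM glutamine present"),
        "pyruvate": L((-1.5, -1.5, -1.5), "medium pyruvate (1 mM) modestly consumed"),
    }
    fresh = {
        "glucose": 25.0, "glutamine": 1.0, "pyruvate": 1.0,
        "lactate": 0.0, "alanine": 0.0, "formate": 0.0, "glutamate": 0.0,
    }
    source_fraction = {
        "glucose": {
            "lactate": L((0.80, 0.80, 0.80),
                         "~80% of released lactate glucose-derived in all lines (n=5)"),
            "alanine": L((0.80, 0.80, 0.80),
                         "~80% of released alanine glucose-derived in all lines"),
        },
        "glutamine": {
            "lactate": L((0.05, 0.05, 0.05), "minor glutamine-derived lactate fraction"),
            "alanine": L((0.05, 0.05, 0.05), "minor glutamine-derived alanine fraction"),
        },
    }
    enrichment = {
        "glucose": {
            "pep": L((0.90, 0.90, 0.90), "~90% of PEP glucose-derived in every line"),
            "pyruvate": L((0.60, 0.80, 0.80), "~60% NSC-34 rising to ~80% in transfectants"),
            "lactate": L((0.60, 0.80, 0.80), "~60% NSC-34 rising to ~80% in transfectants"),
            "alanine": L((0.60, 0.79, 0.77), "alanine 79% WT vs 77% G93A, ~60% NSC-34"),
            "citrate": L((0.50, 0.52, 0.49),
                         "glucose contribution ~40-55% to citrate; small significant "
                         "G93A decrease vs WT"),
            "isocitrate": L((0.48, 0.50, 0.50), "glucose contribution ~40-55%"),
            "succinate": L((0.22, 0.23, 0.24), "succinate ~20-25% from glucose"),
            "fumarate": L((0.40, 0.50, 0.52), "significant increase in transfectants"),
            "malate": L((0.42, 0.52, 0.54), "significant increase in transfectants"),
            "glutamate": L((0.50, 0.50, 0.509),
                           ">=50% of glutamate glucose-derived; +0.9% in G93A"),
            "glutamine": L((0.32, 0.18, 0.24),
                           "glutamine from glucose 32% NSC-34, 18% WT, 24% G93A"),
            "serine": L((0.20, 0.35, 0.45), "serine-synthesis activation in transfectants"),
            "glycine": L((0.15, 0.30, 0.40), "glycine follows serine labeling"),
            "cystathionine": L((0.10, 0.20, 0.30),
                               "cystathionine labeling increased, most in G93A"),
            "aspartate": L((0.35, 0.40, 0.40), "aspartate mirrors OAA labeling"),
        },
        "glutamine": {
            "pep": L((0.05, 0.05, 0.05), "glutamine-derived carbon consistently <10%"),
            "pyruvate": L((0.05, 0.05, 0.05), "glutamine-derived carbon <10%"),
            "lactate": L((0.05, 0.05, 0.05), "glutamine-derived carbon <10%"),
            "alanine": L((0.05, 0.05, 0.05), "glutamine-derived carbon <10%"),
            "citrate": L((0.15, 0.15, 0.15), "glutamine contribution 10-20%"),
            "isocitrate": L((0.13, 0.13, 0.13), "glutamine contribution 10-20%"),
            "succinate": L((0.22, 0.22, 0.22),
                           "succinate 20-25% from glutamine, above isocitrate: oxidative "
                           "entry through alpha-ketoglutarate"),
            "fumarate": L((0.15, 0.15, 0.15), "glutamine contribution 10-20%"),
            "malate": L((0.15, 0.15, 0.15), "glutamine contribution 10-20%"),
            "glutamate": L((0.22, 0.22, 0.22), "20-25% of glutamate glutamine-derived"),
            "glutamine": L((0.39, 0.67, 0.56),
                           "glutamine from tracer glutamine 39% NSC-34, 67% WT, 56% G93A"),
            "serine": L((0.03, 0.03, 0.03), "marginal glutamine contribution"),
            "glycine": L((0.03, 0.03, 0.03), "marginal glutamine contribution"),
            "cystathionine": L((0.03, 0.04, 0.04), "marginal glutamine contribution"),
            "aspartate": L((0.15, 0.15, 0.15), "aspartate mirrors OAA labeling"),
        },
    }
    pool_percent = {
        "gap": L((100, 105, 110), "glyceraldehyde-3-phosphate not significantly changed"),
        "dhap": L((100, 105, 95), "dihydroxyacetone phosphate not significantly changed"),
        "3pg": L((100, 175, 180), "3-phosphoglycerate 70-80% higher in transfectants"),
        "pep": L((100, 361, 138), "PEP +261% WT vs NSC-34 and +162% WT vs G93A"),
        "pyruvate": L((100, 278, 361), "pyruvate +178% WT, +261% G93A vs NSC-34"),
        "lactate": L((100, 200, 210), "intracellular lactate higher in both transfectants"),
        "alanine": L((100, 220, 230), "intracellular alanine higher in both transfectants"),
        "citrate": L((100, 135, 135), "citrate +30-40%, not significant"),
        "isocitrate": L((100, 130, 140), "isocitrate +30-40%, not significant"),
        "succinate": L((100, 100, 100), "succinate unchanged"),
        "fumarate": L((100, 405, 304), "fumarate up to +305% WT; G93A -25% vs WT"),
        "malate": L((100, 345, 210), "malate strongly increased; G93A -39% vs WT"),
        "serine": L((100, 264, 158), "serine +164% WT vs NSC-34; G93A -40% vs WT"),
        "glycine": L((100, 147, 140), "glycine +47% WT, not significant"),
        "glutamine": L((100, 611, 134), "glutamine +511% WT; G93A -78% vs WT"),
        "glutamate": L((100, 200, 190), "glutamate +100% WT vs NSC-34"),
        "asparagine": L((100, 205, 66), "asparagine +105% WT; G93A -68% vs WT"),
        "n-acetylaspartate": L((100, 206, 132), "NAA +106% WT; G93A -36% vs WT"),
        "aspartate": L((100, 177, 160), "aspartate +77% WT, not significant"),
        "leucine": L((100, 100, 49), "leucine -51% in G93A vs NSC-34"),
        "isoleucine": L((100, 100, 49), "isoleucine -51% in G93A"),
        "valine": L((100, 100, 47), "valine -53% in G93A"),
        "cysteine": L((100, 100, 44), "cysteine -56% in G93A"),
        "cystathionine": L((100, 150, 120), "cystathionine pool smaller in G93A than WT"),
    }
    # mechanistic settings per line: qualitative flux splits consistent with
    # the labeling phenotype (higher glycolytic contribution and serine
    # synthesis in the transfectants, glutamine synthetase active everywhere)
    pathway = {
        "NSC-34": PathwayConfig(g=0.60, q=0.8, pc_fraction=0.05,
                                glutamine_anaplerosis=0.3, gs_fraction=0.35,
                                serine_fraction=0.4),
        "WT-NSC": PathwayConfig(g=0.80, q=0.8, pc_fraction=0.05,
                                glutamine_anaplerosis=0.3, gs_fraction=0.20,
                                serine_fraction=0.6),
        "G93A-NSC": PathwayConfig(g=0.80, q=0.8, pc_fraction=0.05,
                                  glutamine_anaplerosis=0.3, gs_fraction=0.25,
                                  serine_fraction=0.7),
    }
    cfg = StudyConfig(
        exchange=exchange,
        fresh_medium_mM=fresh,
        source_fraction=source_fraction,
        enrichment=enrichment,
        pool_percent=pool_percent,
        pathway=pathway,
        seed=seed,
    )
    cfg.validate()
    return cfg


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative mean-one lognormal noise at the given CV."""
    if cv == 0:
        return np.ones(() if size is None else size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _protein_samples(cfg: StudyConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    return cfg.protein_mg_mean * _lognormal_factors(rng, cfg.cv_protein, n)


def generate_media_dataset(
    cfg: StudyConfig,
    seed: int | None = None,
    n_replicates: int | None = None,
    metabolites: tuple[str, ...] | None = None,
):
    """Fresh + spent media concentration tables and a protein table.

    Spent concentrations are ``fresh + truth * protein / volume`` with
    mean-one lognormal measurement noise at ``cv_intensity``; protein varies
    biologically at ``cv_protein`` and is recorded exactly (replicate-plate
    protein assay).  Returns ``(fresh_df, spent_df, protein_df)``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_media if n_replicates is None else n_replicates
    mets = tuple(cfg.exchange) if metabolites is None else metabolites
    fresh_df = pd.DataFrame(
        {"metabolite": list(cfg.fresh_medium_mM), "mM": list(cfg.fresh_medium_mM.values())}
    )
    spent_rows, protein_rows = [], []
    for line in STUDY_LINES:
        protein = _protein_samples(cfg, rng, n)
        for rep in range(n):
            sid = f"{line}_media_{rep}"
            protein_rows.append(
                {"sample_id": sid, "line": line,
                 "protein_mg": protein[rep], "volume_ml": cfg.volume_ml}
            )
            for met in mets:
                truth = cfg.exchange[met].for_line(line)
                # noise acts on the exchange itself, then is converted to a
                # concentration, so a 25 mM glucose baseline does not drown
                # a few-umol difference measurement
                eps = _lognormal_factors(rng, cfg.cv_intensity, None)
                mM = cfg.fresh_medium_mM[met] + truth * eps * protein[rep] / cfg.volume_ml
                if mM < 0:
                    raise ValueError(f"negative spent concentration for {met} ({line})")
                spent_rows.append(
                    {"sample_id": sid, "line": line, "metabolite": met, "mM": mM}
                )
    return fresh_df, pd.DataFrame(spent_rows), pd.DataFrame(protein_rows)


def _true_mid(enrichment: float, n_backbone: int, purity: float) -> np.ndarray:
    """Unlabeled/uniformly-labeled mixture whose atom enrichment is exact.

    The labeled component carries 13C at each backbone position with
    probability ``purity``; its weight is ``enrichment / purity`` so the
    atom-level enrichment equals ``enrichment`` exactly.
    """
    labeled_weight = enrichment / purity
    if labeled_weight > 1 + 1e-12:
        raise ValueError("enrichment exceeds tracer purity")
    # binomial pattern of n positions each 13C with probability `purity`
    from scipy.stats import binom as _binom

    pattern = _binom.pmf(np.arange(n_backbone + 1), n_backbone, purity)
    mid = (1.0 - labeled_weight) * np.eye(1, n_backbone + 1, 0).ravel()
    mid = mid + labeled_weight * pattern
    return mid


def generate_tracer_dataset(cfg: StudyConfig, seed: int | None = None, library=None):
    """Raw GC-MS isotopologue intensities plus NMR integral tables.

    GC-MS: per line x tracer x metabolite, the true MID (atom enrichment
    equal to the configured truth) is pushed through the fragment's
    natural-abundance correction matrix — including all derivatization atoms
    and the tracer purity — scaled to an arbitrary instrument intensity and
    degraded with per-channel multiplicative noise.

    NMR: center/satellite integrals of the lactate and alanine methyl
    resonances, consistent with the configured tracer-source fractions on
    top of the single-site natural 13C background.

    Returns ``(gcms_df, nmr_df)``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if library is None:
        library = load_fragment_library()
    lib = library.set_index("metabolite")
    cms = correction_matrices(library)
    gcms_rows = []
    for tracer, mets in cfg.enrichment.items():
        for line in STUDY_LINES:
            for rep in range(cfg.n_mid):
                sid = f"{line}_{tracer}_{rep}"
                scale = 1e6 * _lognormal_factors(rng, cfg.cv_intensity, None)
                for met, truth in mets.items():
                    if met not in cms:
                        raise ValueError(f"no fragment for {met!r} in library")
                    cm = cms[met]
                    n = int(lib.loc[met, "n_backbone"])
                    mid = _true_mid(truth.for_line(line), n, cfg.tracer_purity)
                    clean = cm.matrix @ mid
                    noisy = clean * scale * _lognormal_factors(
                        rng, cfg.cv_intensity, clean.size
                    )
                    for k, inten in enumerate(noisy):
                        gcms_rows.append(
                            {"sample_id": sid, "line": line, "tracer": tracer,
                             "metabolite": met,
                             "fragment_id": lib.loc[met, "fragment_id"],
                             "shift": k, "intensity": inten}
                        )
    nmr_rows = []
    for tracer, mets in cfg.source_fraction.items():
        for line in STUDY_LINES:
            for rep in range(cfg.n_mid):
                sid = f"{line}_{tracer}_{rep}"
                for met, truth in mets.items():
                    t = truth.for_line(line)
                    f13 = NATURAL_13C + t * (1.0 - NATURAL_13C)
                    total = 1000.0 * _lognormal_factors(rng, cfg.cv_intensity, None)
                    center = total * (1 - f13) * _lognormal_factors(
                        rng, cfg.cv_intensity, None
                    )
                    sat = total * f13 * _lognormal_factors(rng, cfg.cv_intensity, None)
                    tsp = 100.0 * _lognormal_factors(rng, cfg.cv_intensity, None)
                    nmr_rows.append(
                        {"sample_id": sid, "line": line, "tracer": tracer,
                         "metabolite": met, "resonance": f"{met}_CH3",
                         "center": center, "satellites": sat, "tsp": tsp,
                         "protons": 3}
                    )
    return pd.DataFrame(gcms_rows), pd.DataFrame(nmr_rows)


def generate_pool_dataset(
    cfg: StudyConfig,
    seed: int | None = None,
    missingness: float = 0.0,
    baseline_au: float = 1000.0,
):
    """Profiling intensity table with internal-standard and protein columns.

    Per-line fold-changes are applied to an arbitrary baseline abundance;
    per-sample internal-standard response and protein content are injected
    (and recorded) so that normalization can remove them; a ``missingness``
    fraction of cells is dropped at random for back-fill testing.
    """
    cfg.validate()
    if not 0 <= missingness < 1:
        raise ValueError("missingness must be in [0, 1)")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rows = []
    for line in STUDY_LINES:
        protein = _protein_samples(cfg, rng, cfg.n_pool)
        is_factor = _lognormal_factors(rng, cfg.cv_is, cfg.n_pool)
        for rep in range(cfg.n_pool):
            sid = f"{line}_pool_{rep}"
            for met, truth in cfg.pool_percent.items():
                raw = (
                    baseline_au
                    * truth.for_line(line) / 100.0
                    * protein[rep]
                    * is_factor[rep]
                    * _lognormal_factors(rng, cfg.cv_intensity, None)
                )
                rows.append(
                    {"sample_id": sid, "line": line, "metabolite": met,
                     "quant_ion_intensity": raw,
                     "is_intensity": 1000.0 * is_factor[rep],
                     "protein_mg": protein[rep]}
                )
    df = pd.DataFrame(rows)
    if missingness > 0:
        keep = rng.random(len(df)) >= missingness
        # never drop a whole metabolite
        for met in cfg.pool_percent:
            sel = df["metabolite"] == met
            if not keep[sel.to_numpy()].any():
                keep[np.flatnonzero(sel.to_numpy())[0]] = True
        df = df[keep].reset_index(drop=True)
    return df
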