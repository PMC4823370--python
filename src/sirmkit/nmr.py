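"""Media metabolite quantification, exchange fluxes, and 13C-satellite attribution.

Works on integral tables extracted from 1H NMR spectra of culture media, not
on raw FIDs.  Concentrations are referenced to a TSP internal standard;
consumption/release fluxes are normalized to cell protein; the 13C satellite
doublets flanking a proton resonance report the labeling of the attached
carbon and hence the tracer-derived fraction of the molecule at that
position.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "NATURAL_13C",
    "NmrIntegralRecord",
    "ExchangeRecord",
    "quantify_concentration",
    "net_exchange",
    "ratio_per_glucose",
    "satellite_fraction",
]

NATURAL_13C = 0.0107  # single-carbon natural 13C abundance

# 550 uL medium + 50 uL TSP/D2O: analyte diluted 600/550 relative to TSP basis
DEFAULT_DILUTION = 600.0 / 550.0


@dataclass
class NmrIntegralRecord:
    """Integrals of one resonance: 12C center peak, summed 13C satellites, TSP."""

    sample_id: str
    metabolite: str
    resonance: str
    center: float
    satellites: float
    tsp: float
    protons: int

    def __post_init__(self) -> None:
        if self.center < 0 or self.satellites < 0:
            raise ValueError("integrals must be non-negative")
        if self.tsp <= 0:
            raise ValueError("TSP integral must be positive")
        if self.protons <= 0:
            raise ValueError("proton count must be positive")


@dataclass
class ExchangeRecord:
    """Signed media exchange: negative = consumed, positive = released."""

    sample_id: str
    metabolite: str
    fresh_mM: float
    end_mM: float
    volume_mL: float
    protein_mg: float

    @property
    def umol_per_mg(self) -> float:
        return net_exchange(self.fresh_mM, self.end_mM, self.volume_mL, self.protein_mg)


def quantify_concentration(
    r: NmrIntegralRecord,
    tsp_conc_mM: float = 11.6 / 12.0,
    tsp_protons: int = 9,
    dilution: float = DEFAULT_DILUTION,
) -> float:
    """Concentration (mM) from integral ratio to the TSP internal standard.

    ``conc = (total / tsp) * (tsp_protons / protons) * tsp_conc * dilution``.
    The default TSP concentration is the in-tube value of a 50 uL spike of
    11.6 mM TSP into 550 uL of medium; the dilution factor scales back to
    the neat-medium concentration.  The total integral includes the 13C
    satellites so labeling does not bias quantification.
    """
    total = r.center + r.satellites
    return total / r.tsp * (tsp_protons / r.protons) * tsp_conc_mM * dilution


def net_exchange(fresh_mM: float, end_mM: float, volume_mL: float, protein_mg: float) -> float:
    """Net exchange in umol per mg protein; negative values are consumption.

    Metabolites absent from fresh medium (lactate, alanine, formate,
    glutamate) have ``fresh_mM = 0`` and are pure release.
    """
    if protein_mg <= 0:
        raise ValueError("protein must be positive")
    if volume_mL <= 0:
        raise ValueError("volume must be positive")
    return (end_mM - fresh_mM) * volume_mL / protein_mg


def ratio_per_glucose(release_umol_mg: float, glucose_exchange_umol_mg: float) -> float:
    """Moles released per mole of glucose consumed (cell-number independent)."""
    if glucose_exchange_umol_mg >= 0:
        raise ValueError("glucose must be net consumed (exchange < 0) for this ratio")
    return release_umol_mg / abs(glucose_exchange_umol_mg)


def satellite_fraction(r: NmrIntegralRecord) -> tuple[float, float]:
    """(f13, tracer_fraction) at the observed carbon position.

    ``f13`` is the fraction of molecules 13C-labeled at the observed carbon,
    ``satellites / (center + satellites)``.  The tracer-derived fraction
    subtracts the single-site natural 13C background:
    ``(f13 - 0.0107) / (1 - 0.0107)``, clipped to [0, 1].
    """
    total = r.center + r.satellites
    if total <= 0:
        raise ValueError("zero total intensity")
    f13 = r.satellites / total
    tracer = (f13 - NATURAL_13C) / (1.0 - NATURAL_13C)
    return f13, min(1.0, max(0.0, tracer))


def exchange_from_tables(fresh_df, spent_df, protein_df):
    """Per-sample signed exchange table from media + protein tables.

    ``fresh_df``: metabolite, mM.  ``spent_df``: sample_id, metabolite, mM
    (plus metadata).  ``protein_df``: sample_id, protein_mg, volume_ml.
    Returns one row per (sample, metabolite) with ``umol_per_mg``.
    """
    import pandas as pd

    fresh = fresh_df.set_index("metabolite")["mM"]
    prot = protein_df.set_index("sample_id")
    rows = []
    for _, r in spent_df.iterrows():
        met = r["metabolite"]
        if met not in fresh.index:
            raise ValueError(f"metabolite {met!r} missing from fresh-medium table")
        p = prot.loc[r["sample_id"]]
        rows.append(
            {
                "sample_id": r["sample_id"],
                "metabolite": met,
                "umol_per_mg": net_exchange(
                    float(fresh[met]), float(r["mM"]),
                    float(p["volume_ml"]), float(p["protein_mg"]),
                ),
            }
            | {k: r[k] for k in spent_df.columns if k not in ("sample_id", "metabolite", "mM")}
        )
    return pd.DataFrame(rows)


def satellite_table(nmr_df):
    """Apply :func:`satellite_fraction` to a long NMR integral table.

    Expects columns sample_id, metabolite, resonance, center, satellites,
    tsp, protons; metadata columns are carried through.
    """
    import pandas as pd

    rows = []
    for _, r in nmr_df.iterrows():
        rec = NmrIntegralRecord(
            sample_id=r["sample_id"], metabolite=r["metabolite"],
            resonance=r["resonance"], center=float(r["center"]),
            satellites=float(r["satellites"]), tsp=float(r["tsp"]),
            protons=int(r["protons"]),
        )
        f13, tracer = satellite_fraction(rec)
        rows.append(
            {k: r[k] for k in nmr_df.columns}
            | {"f13": f13, "tracer_fraction": tracer}
        )
    return pd.DataFrame(rows)
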