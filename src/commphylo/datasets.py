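"""Published reference tables for the Mt. Wilhelm geometrid moth gradient.

Eight rainforest sites on the slope of Mt. Wilhelm (Papua New Guinea) were
sampled at 500 m elevational increments from the lowlands (200 m a.s.l.) to
the timberline (3700 m). The values here are the published per-site
community-phylogenetic indices (NRI, NTI, SES.PD, computed from a 604-species
COI-barcode phylogeny and 1,390 site x species occurrences) together with
the three standardized predictors used to model them: woody plant species
richness, a combined insectivorous-predator abundance index, and mean annual
temperature. Predictors are z-scores; the phylogenetic indices are on their
natural (standard-deviation) scale.

These printed tables are inputs: they let the modelling machinery be run and
checked without access to the underlying sequence data.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "mt_wilhelm_indices",
    "mt_wilhelm_site_counts",
    "MT_WILHELM_TEMPERATURE",
]

# Mean annual temperature model along the transect: linear lapse from the
# lowland reference site, as measured by data loggers.
MT_WILHELM_TEMPERATURE = {
    "intercept_c": 27.4,     # deg C at the 200 m reference site
    "lapse_c_per_100m": 0.54,
    "base_elevation_m": 200.0,
    "timberline_c": 8.37,    # observed at 3700 m (not exactly collinear
    "timberline_elevation_m": 3700.0,  # with the stated lapse rate)
}

_INDICES = [
    # site, elevation, NRI, NTI, SES.PD, plant_z, predator_z, temperature_z
    ("Kausi", 200, 0.21, 2.51, -2.22, -0.22, 1.51, 1.48),
    ("Bobvrai", 700, -0.08, 1.21, -0.88, 1.11, 1.19, 1.08),
    ("Koviamarai", 1200, -0.31, -0.35, 0.69, 1.26, 0.53, 0.56),
    ("Bananumbu", 1700, 2.81, 1.32, -1.35, 0.54, -0.11, 0.36),
    ("Sinopass", 2200, 3.05, 2.11, -2.59, -0.84, -0.43, -0.14),
    ("Kiagimanigi", 2700, 1.66, 4.60, -5.43, 0.29, -0.05, -0.59),
    ("Kombugo Manuno", 3200, 0.10, 4.61, -4.43, -0.12, -0.87, -1.19),
    ("Piunde Lake", 3700, 2.63, 2.18, -3.11, -2.01, -1.76, -1.55),
]

_COUNTS = [
    # site, elevation, abundance, morphospecies, sequenced species
    ("Kausi", 200, 2311, 201, 179),
    ("Bobvrai", 700, 1805, 239, 198),
    ("Koviamarai", 1200, 2194, 391, 283),
    ("Bananumbu", 1700, 3903, 403, 289),
    ("Sinopass", 2200, 2631, 305, 232),
    ("Kiagimanigi", 2700, 1134, 197, 156),
    ("Kombugo Manuno", 3200, 2091, 182, 45),
    ("Piunde Lake", 3700, 355, 37, 8),
]


def mt_wilhelm_indices() -> pd.DataFrame:
    """Published per-site phylogenetic indices and z-scored predictors."""
    return pd.DataFrame(
        _INDICES,
        columns=[
            "site",
            "elevation",
            "nri",
            "nti",
            "ses_pd",
            "plant_richness",
            "predator_abundance",
            "temperature",
        ],
    )


def mt_wilhelm_site_counts() -> pd.DataFrame:
    """Published per-site abundance and species counts along the transect."""
    return pd.DataFrame(
        _COUNTS,
        columns=["site", "elevation", "abundance", "morphospecies", "sequenced_species"],
    )
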