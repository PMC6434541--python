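"""Experimental design: sites, climate treatments, and plot identity.

The experiment crosses 3 prairie sites along a latitudinal gradient with
4 climate treatments (control, drought, warming, warming + additional
precipitation), replicated 5 times per site-treatment cell: 60 plots.
Because drought manipulates only moisture and warming_ppt restores
moisture under warming, the treatments collapse into two temperature
categories: ambient (control, drought) and warming (warming, warming_ppt).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

SITES = ("southern", "central", "northern")
TREATMENTS = ("control", "drought", "warming", "warming_ppt")
N_REPLICATES = 5

#: ambient vs warming category per treatment
TEMPERATURE_CATEGORY = {
    "control": "ambient",
    "drought": "ambient",
    "warming": "warming",
    "warming_ppt": "warming",
}

_SITE_CODE = {"southern": "S", "central": "C", "northern": "N"}
_TRT_CODE = {"control": "C", "drought": "D", "warming": "W", "warming_ppt": "WP"}


@dataclass(frozen=True)
class PlotDesign:
    """Identity of one experimental plot."""

    site: str
    treatment: str
    replicate: int
    plot_id: str

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if not 1 <= int(self.replicate) <= N_REPLICATES:
            raise ValueError(f"replicate must be 1..{N_REPLICATES}, got {self.replicate}")

    @property
    def temperature_category(self) -> str:
        return TEMPERATURE_CATEGORY[self.treatment]


def make_plot_id(site: str, treatment: str, replicate: int) -> str:
    return f"{_SITE_CODE[site]}-{_TRT_CODE[treatment]}-{replicate}"


def full_design() -> pd.DataFrame:
    """The complete 3 sites x 4 treatments x 5 replicates = 60-plot design.

    Returns a DataFrame with columns site, treatment, replicate, plot_id,
    temperature_category.
    """
    rows = [
        {
            "site": s,
            "treatment": t,
            "replicate": r,
            "plot_id": make_plot_id(s, t, r),
            "temperature_category": TEMPERATURE_CATEGORY[t],
        }
        for s in SITES
        for t in TREATMENTS
        for r in range(1, N_REPLICATES + 1)
    ]
    return pd.DataFrame(rows)


def validate_design(design: pd.DataFrame) -> None:
    """Check that a design table is a valid (subset of a) full design."""
    required = {"site", "treatment", "replicate", "plot_id"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if design["plot_id"].duplicated().any():
        dups = design.loc[design["plot_id"].duplicated(), "plot_id"].tolist()
        raise ValueError(f"duplicate plot_ids in design: {dups}")
    bad_site = set(design["site"]) - set(SITES)
    if bad_site:
        raise ValueError(f"unknown sites in design: {sorted(bad_site)}")
    bad_trt = set(design["treatment"]) - set(TREATMENTS)
    if bad_trt:
        raise ValueError(f"unknown treatments in design: {sorted(bad_trt)}")
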