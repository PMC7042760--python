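"""Composite land-use intensity (LUI) index.

LUI averages four z-standardized components per site: (a) annual plant
biomass removal, (b) agricultural inputs, (c) dissimilarity of vegetation
structure to natural habitats of the same elevational band, and (d) the
proportion of agriculturally managed land in the surrounding landscape.
Component (c) is computed here from raw vegetation-structure vectors;
(a), (b) and (d) are supplied as inputs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VEG_COLUMNS = ("canopy_closure", "canopy_height", "veg_heterogeneity")
COMPONENT_COLUMNS = ("biomass_removal", "agri_inputs", "veg_dissimilarity", "landscape_agri_prop")


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=0)
    if not np.isfinite(sd) or sd == 0:
        logger.warning("component %r has zero variance; contributes 0 to LUI", x.name)
        return pd.Series(np.zeros(len(x)), index=x.index, name=x.name)
    return (x - x.mean()) / sd


def vegetation_dissimilarity(
    sites: pd.DataFrame,
    band_col: str = "elevation_level",
    natural_col: str = "is_natural",
    veg_cols: tuple[str, ...] = VEG_COLUMNS,
) -> pd.Series:
    """Euclidean distance of each site's vegetation structure to the natural
    reference of its elevational band.

    Raw structure changes with elevation independently of land use (savanna
    vs forest), so each component is first z-scored across all sites and
    each site is then compared with the mean vector over *natural* sites of
    the same band.  A band without a natural reference site is an error.
    """
    z = sites[list(veg_cols)].apply(_zscore)
    out = pd.Series(np.nan, index=sites.index, name="veg_dissimilarity")
    for band, idx in sites.groupby(band_col).groups.items():
        natural = idx[sites.loc[idx, natural_col].astype(bool)]
        if len(natural) == 0:
            raise ValueError(f"no natural reference site in elevational band {band!r}")
        ref = z.loc[natural].mean(axis=0)
        diffs = z.loc[idx] - ref
        out.loc[idx] = np.sqrt((diffs**2).sum(axis=1))
    return out


def compute_lui(
    components: pd.DataFrame,
    component_cols: tuple[str, ...] = COMPONENT_COLUMNS,
    standardize: str = "zscore",
) -> pd.Series:
    """Average the z-standardized components into the final LUI per site.

    A missing component value is ignored for that site (mean over the
    available components, with a logged warning); a zero-variance component
    contributes 0 for all sites.  ``standardize`` may be "zscore" (default)
    or "minmax".
    """
    if len(components) < 2:
        raise ValueError("LUI standardization needs at least two sites")
    cols = [c for c in component_cols if c in components.columns]
    if not cols:
        raise ValueError("no LUI component columns present")
    if standardize == "zscore":
        z = components[cols].apply(_zscore)
    elif standardize == "minmax":
        z = components[cols].apply(
            lambda x: (x - x.min()) / (x.max() - x.min()) if x.max() > x.min() else x * 0.0
        )
    else:
        raise ValueError(f"unknown standardization {standardize!r}")
    if components[cols].isna().any().any():
        logger.warning("missing LUI component values; averaging available components per site")
    lui = z.mean(axis=1, skipna=True)
    lui.name = "LUI"
    return lui
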