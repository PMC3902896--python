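"""Bundled reference data.

The package ships the seven-HRE glucocorticoid receptor reference panel
(sequence, K_app, K_tot, fold-activation) used throughout the analyses and
examples.  Values are stored in their printed units (nM, fM2) and converted
to canonical molar / molar-squared on load.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .binding_core import FM2, NM, HRERecord

__all__ = ["load_reference_hres", "reference_hre_frame"]


def reference_hre_frame() -> pd.DataFrame:
    """Return the bundled HRE reference panel as a DataFrame (printed units)."""
    with resources.files("srbind.data").joinpath("hre_reference.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def load_reference_hres() -> list[HRERecord]:
    """Load the bundled GR-HRE panel as :class:`HRERecord` objects.

    Affinities are converted to molar (K_app) and molar squared (K_tot).
    """
    df = reference_hre_frame()
    return [
        HRERecord(
            name=row["name"],
            sequence=row["sequence"],
            k_app=row["k_app_nm"] * NM,
            k_app_sd=row["k_app_sd_nm"] * NM,
            k_tot=row["k_tot_fm2"] * FM2,
            k_tot_sd=row["k_tot_sd_fm2"] * FM2,
            fold_activation=row["fold_activation"],
            fa_sem=row["fa_sem"],
        )
        for _, row in df.iterrows()
    ]
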