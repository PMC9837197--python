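"""CSV and YAML readers/writers for incomplete data and priors.

The sole data format is rectangular numeric CSV with a header row; missing
cells are encoded as an empty field or the token ``"NA"`` (both are
recognized on read).  Prior files are flat YAML with keys ``mu0`` (list),
``tau``, ``m``, ``Lambda`` (list of rows) and optionally ``convention``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fcs import IncompleteData
from .priors import DEFAULT_CONVENTION, NIGPrior, NIWPrior

__all__ = [
    "read_csv_missing",
    "write_csv_missing",
    "load_prior_yaml",
    "dump_prior_yaml",
    "nig_to_mapping",
]

MISSING_TOKEN = "NA"


def read_csv_missing(path, missing_token: str = MISSING_TOKEN) -> IncompleteData:
    """Read a numeric CSV with missing cells into an IncompleteData.

    Empty fields and ``missing_token`` both mark missing cells; any other
    non-numeric observed cell is an error.
    """
    df = pd.read_csv(
        path,
        na_values=[missing_token, ""],
        keep_default_na=False,
        float_precision="round_trip",
    )
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as err:
        raise ValueError(f"non-numeric observed cell in {path}: {err}") from err
    return IncompleteData(values, np.isnan(values), tuple(str(c) for c in df.columns))


def write_csv_missing(
    data: IncompleteData | pd.DataFrame,
    path,
    missing_token: str = MISSING_TOKEN,
) -> None:
    """Write data to CSV, encoding missing cells as ``missing_token``.

    Round-trips bit-exactly with :func:`read_csv_missing` (full float
    precision is kept)."""
    if isinstance(data, IncompleteData):
        df = data.to_dataframe()
    else:
        df = data
    df.to_csv(path, index=False, na_rep=missing_token, float_format="%.17g")


def load_prior_yaml(path) -> NIWPrior:
    """Load an NIW prior from a flat YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return NIWPrior(
        mu0=np.asarray(raw["mu0"], dtype=float),
        tau=float(raw["tau"]),
        m=float(raw["m"]),
        Lambda=np.asarray(raw["Lambda"], dtype=float),
        convention=raw.get("convention", DEFAULT_CONVENTION),
    )


def dump_prior_yaml(prior: NIWPrior, path=None) -> str:
    """Serialize an NIW prior to YAML; write to ``path`` when given."""
    payload = {
        "mu0": prior.mu0.tolist(),
        "tau": prior.tau,
        "m": prior.m,
        "Lambda": prior.Lambda.tolist(),
        "convention": prior.convention,
    }
    text = yaml.safe_dump(payload, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def nig_to_mapping(prior: NIGPrior) -> dict:
    """Plain mapping of an NIG prior (for YAML printing by the CLI)."""
    return {
        "sigma_df": prior.sigma_df,
        "sigma_scale": prior.sigma_scale,
        "coef_mean": prior.coef_mean.tolist(),
        "coef_scale": prior.coef_scale.tolist(),
    }
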