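"""Light NetCDF/CSV persistence for the pipeline's products.

NetCDF goes through xarray's scipy backend (NetCDF3 classic), which keeps
the files portable without a compiled NetCDF4 stack; 64-bit integers are
downcast on write because the classic format has no int64.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["save_netcdf", "load_netcdf", "save_truth_table"]


def _nc3_safe(ds: xr.Dataset) -> xr.Dataset:
    out = ds.copy()
    for name, var in list(out.variables.items()):
        if var.dtype == np.int64:
            out[name] = var.astype(np.int32)
        elif var.dtype == bool:
            out[name] = var.astype(np.int8)
    return out


def save_netcdf(obj: xr.Dataset | xr.DataArray, path) -> None:
    ds = obj.to_dataset() if isinstance(obj, xr.DataArray) else obj
    _nc3_safe(ds).to_netcdf(path, engine="scipy")


def load_netcdf(path) -> xr.Dataset:
    return xr.load_dataset(path, engine="scipy")


def save_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)
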