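"""Delimited-text and JSON input/output for all pipeline artifacts.

Tables are plain CSV with headers; results are JSON.  Readers validate
the expected columns and raise a parse error naming the file.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

TRIAL_COLUMNS = ["subject", "condition", "modality", "rate_diff",
                 "duration_jitter_ms", "response_faster", "prev_modality"]

CAUSAL_COLUMNS = ["subject", "rate_hz", "prop_sync", "max_offset_s",
                  "response_common"]


class ParseError(ValueError):
    pass


def write_trial_table(table: pd.DataFrame, path):
    table.to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    # empty prev_modality cells round-trip as NaN -> None-like
    return df


def write_causal_table(table: pd.DataFrame, path):
    table.to_csv(path, index=False)


def read_causal_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CAUSAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def write_ccg_table(result, path):
    """CCG difference function as (lag_ms, diff, lower95, upper95, sig)."""
    df = pd.DataFrame({"lag_ms": result.lags_ms, "diff": result.diff})
    if result.lower95 is not None:
        df["lower95"] = result.lower95
        df["upper95"] = result.upper95
        df["sig"] = result.significant
    df.to_csv(path, index=False, float_format="%.12g")


def read_ccg_table(path):
    from .ccg_analysis import CCGDifference

    df = pd.read_csv(path)
    if "lag_ms" not in df.columns or "diff" not in df.columns:
        raise ParseError(f"{path}: not a CCG table")
    kw = {}
    if "lower95" in df.columns:
        kw = {"lower95": df["lower95"].to_numpy(),
              "upper95": df["upper95"].to_numpy(),
              "significant": df["sig"].to_numpy(int)}
    return CCGDifference(df["lag_ms"].to_numpy(), df["diff"].to_numpy(), **kw)


def write_json(obj, path):
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if hasattr(o, "to_json_dict"):
            return o.to_json_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=default)


def read_json(path):
    with open(path) as fh:
        try:
            return json.load(fh)
        except json.JSONDecodeError as e:
            raise ParseError(f"{path}: line {e.lineno}: {e.msg}") from e


def read_glmm_fit(path):
    from .glmm import GLMMFit

    d = read_json(path)
    return GLMMFit(beta=d["beta"],
                   random_intercept_sd=d["random_intercept_sd"],
                   loglik=d["loglik"],
                   vcov=np.asarray(d.get("vcov", [])),
                   term_names=list(d["beta"].keys()),
                   converged=d.get("converged", True),
                   ci90={k: tuple(v) for k, v in d.get("ci90", {}).items()},
                   bootstrap_p=d.get("bootstrap_p", {}),
                   n_boot_failed=d.get("n_boot_failed", 0))


def write_glmm_fit(fit, path):
    d = fit.to_json_dict()
    d["vcov"] = np.asarray(fit.vcov).tolist()
    write_json(d, path)
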