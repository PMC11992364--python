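"""Synthetic single-cell tables emulating segmented half-domain microscopy data.

The real experiment images a ~5,400 × 330 μm stripe crossing the light-dark
border and segments every cell, yielding a per-object table: identity
(emitter/receiver), position along the experimental axis, area in pixels and
mean GFP intensity — extended here with cell length (μm) and ellipse
orientation (degrees). This module generates tables with the same schema
whose receiver readouts follow the closed-form gradient model plus explicit
noise, so that the whole inference pipeline can be exercised and calibrated
without any microscopy data.

Generated structure:

* positions are i.i.d. uniform over the stripe (the experiment seeds a
  spatially homogeneous random cell layer);
* GFP is the n = 1 Hill response of the local concentration times a
  mean-one lognormal factor (multiplicative expression noise);
* cell length is the switch-like Hill response, either as a noisy mean-field
  value per cell or as a bimodal round/elongated mixture whose mixture
  weight is the Hill probability (the population-level mean is identical in
  both modes);
* orientations are uniform on (0, 180]: the experiment found no alignment
  of elongated cells to the large-scale gradient, and the generator encodes
  that null by construction;
* emitters carry identity, position and area only (the analysis quantifies
  receivers).

All randomness flows from a single seed; the same seed reproduces the table
byte for byte.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .profiles import GradientShape, ResponseParams, hill_response, concentration

__all__ = [
    "PopulationConfig",
    "NoiseConfig",
    "generate_cells",
    "simulate_gfp",
    "simulate_length",
    "simulate_orientation",
    "generate_dataset",
    "write_table",
    "read_table",
    "SchemaError",
    "COLUMNS",
    "REQUIRED_COLUMNS",
]

COLUMNS = [
    "cell_id",
    "identity",
    "x_um",
    "area_px",
    "gfp_au",
    "length_um",
    "orientation_deg",
]
#: minimal schema (the four columns the segmentation pipeline always emits)
REQUIRED_COLUMNS = ["identity", "x_um", "area_px", "gfp_au"]

#: round-cell baseline diameter, μm (one yeast cell diameter)
ROUND_CELL_UM = 5.0
#: pixels of segmented area per μm of cell length (invented imaging scale;
#: chosen so the 200-px area cutoff separates round from elongated cells)
_AREA_PX_PER_UM = 24.0
_AREA_PX_SD = 12.0


@dataclass(frozen=True)
class PopulationConfig:
    """Stripe geometry and cell counts.

    Defaults emulate the half-domain experiment: ≈6,700 receivers analyzed
    over a ±2,700 μm window around the border, in a 330-μm-wide stripe.
    """

    x_range: tuple[float, float] = (-2700.0, 2700.0)
    n_receivers: int = 6686
    n_emitters: int = 6686
    stripe_width: float = 330.0

    def __post_init__(self) -> None:
        if not self.x_range[1] > self.x_range[0]:
            raise ValueError("x_range must satisfy max > min")
        if self.n_receivers < 0 or self.n_emitters < 0:
            raise ValueError("cell counts must be nonnegative")


@dataclass(frozen=True)
class NoiseConfig:
    """Single-cell noise magnitudes and morphology mode.

    ``gfp_cv`` — coefficient of variation of the mean-one lognormal factor
    multiplying the GFP mean (default 0.30, typical yeast gene-expression
    variability). ``length_sd`` — additive Gaussian SD on cell length in μm.
    ``morphology_mode`` — "mean_field" (noisy continuous length) or
    "bimodal" (round/elongated mixture).
    """

    gfp_cv: float = 0.30
    length_sd: float = 1.5
    morphology_mode: str = "mean_field"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gfp_cv < 0 or self.length_sd < 0:
            raise ValueError("noise magnitudes must be nonnegative")
        if self.morphology_mode not in ("mean_field", "bimodal"):
            raise ValueError(
                "morphology_mode must be 'mean_field' or 'bimodal'"
            )


def generate_cells(pop: PopulationConfig, seed: int) -> pd.DataFrame:
    """Draw cell positions and identities.

    Positions are i.i.d. uniform over ``pop.x_range``; receivers come first,
    then emitters. Readout columns are initialized absent (NaN).
    """
    rng = np.random.default_rng(seed)
    n = pop.n_receivers + pop.n_emitters
    x = rng.uniform(pop.x_range[0], pop.x_range[1], size=n)
    identity = np.array(
        ["receiver"] * pop.n_receivers + ["emitter"] * pop.n_emitters
    )
    df = pd.DataFrame(
        {
            "cell_id": [f"cell{i:06d}" for i in range(n)],
            "identity": identity,
            "x_um": x,
            "area_px": np.nan,
            "gfp_au": np.nan,
            "length_um": np.nan,
            "orientation_deg": np.nan,
        }
    )
    # emitters are round cells; give them a plausible segmented area
    n_e = pop.n_emitters
    if n_e:
        area = rng.normal(_AREA_PX_PER_UM * ROUND_CELL_UM, _AREA_PX_SD, size=n_e)
        df.loc[df.identity == "emitter", "area_px"] = np.round(
            np.clip(area, 30.0, None)
        )
    return df


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv ** 2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_gfp(
    records: pd.DataFrame,
    shape: GradientShape,
    resp_g: ResponseParams,
    noise: NoiseConfig,
    rng: np.random.Generator,
    geometry: str = "source",
) -> pd.DataFrame:
    """Attach GFP readouts to receiver rows.

    gfp_i = (A_g·θ(x_i) + b_g) · lognormal(1, gfp_cv); the expectation equals
    the model mean. The gene-expression channel is non-cooperative, so
    ``resp_g.n`` must be 1.
    """
    if resp_g.n != 1:
        raise ValueError("gene-expression channel requires Hill coefficient n = 1")
    out = records.copy()
    mask = out.identity == "receiver"
    x = out.loc[mask, "x_um"].to_numpy(dtype=float)
    mean = resp_g.A * hill_response(concentration(x, shape, geometry), 1) + resp_g.b
    out.loc[mask, "gfp_au"] = mean * _lognormal_factor(rng, noise.gfp_cv, x.size)
    return out


def simulate_length(
    records: pd.DataFrame,
    shape: GradientShape,
    resp_m: ResponseParams,
    noise: NoiseConfig,
    rng: np.random.Generator,
    geometry: str = "source",
) -> pd.DataFrame:
    """Attach cell lengths (and length-derived areas) to receiver rows.

    mean_field mode: length = A_m·θ_m(x) + b_m + N(0, length_sd), clipped
    positive. bimodal mode: each cell is elongated with probability θ_m(x)
    (length centered on b_m + A_m) or round (length centered on b_m), so the
    per-bin mean is A_m·θ_m + b_m in both modes.
    """
    out = records.copy()
    mask = out.identity == "receiver"
    x = out.loc[mask, "x_um"].to_numpy(dtype=float)
    theta = np.asarray(
        hill_response(concentration(x, shape, geometry), resp_m.n)
    )
    if noise.morphology_mode == "mean_field":
        length = resp_m.A * theta + resp_m.b
        if noise.length_sd > 0:
            length = length + rng.normal(0.0, noise.length_sd, size=x.size)
    else:
        elongated = rng.uniform(size=x.size) < theta
        center = np.where(elongated, resp_m.b + resp_m.A, resp_m.b)
        length = center + (
            rng.normal(0.0, noise.length_sd, size=x.size)
            if noise.length_sd > 0
            else 0.0
        )
    length = np.clip(length, 0.1, None)
    out.loc[mask, "length_um"] = length
    area = rng.normal(_AREA_PX_PER_UM * length, _AREA_PX_SD)
    out.loc[mask, "area_px"] = np.round(np.clip(area, 30.0, None))
    return out


def simulate_orientation(
    records: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Attach i.i.d. uniform orientations on (0, 180] to receiver rows.

    0° means the cell's long axis is perpendicular to the border (pointing
    up-gradient); uniformity encodes the observed absence of gradient
    alignment.
    """
    out = records.copy()
    mask = out.identity == "receiver"
    n = int(mask.sum())
    out.loc[mask, "orientation_deg"] = 180.0 - rng.uniform(0.0, 180.0, size=n)
    return out


def generate_dataset(
    pop: PopulationConfig,
    shape: GradientShape,
    resp_g: ResponseParams,
    resp_m: ResponseParams,
    noise: NoiseConfig,
    seed: int,
    geometry: str = "source",
) -> pd.DataFrame:
    """Full pipeline: positions → GFP → length/area → orientation.

    A single ``seed`` drives every random draw; identical seeds give
    byte-identical tables.
    """
    df = generate_cells(pop, seed)
    rng = np.random.default_rng(seed + 1)
    df = simulate_gfp(df, shape, resp_g, noise, rng, geometry)
    df = simulate_length(df, shape, resp_m, noise, rng, geometry)
    df = simulate_orientation(df, rng)
    return df


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

class SchemaError(ValueError):
    """Raised when a cell table does not conform to the expected schema."""


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a cell table as CSV with a commented YAML metadata header.

    ``metadata`` (seed, generator parameters, …) is embedded as '# '-prefixed
    YAML lines before the header so a single file is self-describing.
    """
    with open(path, "w") as fh:
        if metadata:
            meta_yaml = yaml.safe_dump(metadata, sort_keys=True)
            for line in meta_yaml.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a cell table written by :func:`write_table` (or the four-column
    segmentation-pipeline variant) and its metadata.

    Files carrying only the minimal schema (identity, x_um, area_px, gfp_au)
    are accepted; length/orientation come back as NaN and a missing cell_id
    is auto-assigned. A missing required column raises :class:`SchemaError`;
    an unparseable row raises ``ValueError`` naming the offending line.
    """
    meta_lines: list[str] = []
    data_lines: list[str] = []
    line_numbers: list[int] = []  # 1-based file line of each data line
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.lstrip().startswith("#"):
                meta_lines.append(line.lstrip()[1:].lstrip("\n").removeprefix(" "))
            elif line.strip():
                data_lines.append(line)
                line_numbers.append(lineno)
    metadata = yaml.safe_load("\n".join(meta_lines)) if meta_lines else {}
    if metadata is None:
        metadata = {}
    if not data_lines:
        raise SchemaError(f"{path}: no data rows")

    header = [h.strip() for h in data_lines[0].split(",")]
    missing = [c for c in REQUIRED_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    n_fields = len(header)
    for row_text, lineno in zip(data_lines[1:], line_numbers[1:]):
        if len(row_text.rstrip("\n").split(",")) != n_fields:
            raise ValueError(
                f"{path}: malformed row at line {lineno}: expected "
                f"{n_fields} fields"
            )

    df = pd.read_csv(io.StringIO("".join(data_lines)))
    numeric = ["x_um", "area_px", "gfp_au", "length_um", "orientation_deg"]
    for col in [c for c in numeric if c in df.columns]:
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at line "
                f"{line_numbers[row + 1]}"
            )
        df[col] = coerced

    if "cell_id" not in df.columns:
        df.insert(0, "cell_id", [f"cell{i:06d}" for i in range(len(df))])
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[COLUMNS], metadata


def default_metadata(
    pop: PopulationConfig,
    shape: GradientShape,
    resp_g: ResponseParams,
    resp_m: ResponseParams,
    noise: NoiseConfig,
    seed: int,
    geometry: str = "source",
) -> dict:
    """Fully resolved generator settings, suitable for the file header."""
    return {
        "seed": seed,
        "geometry": geometry,
        "population": asdict(pop) | {"x_range": list(pop.x_range)},
        "gradient": asdict(shape),
        "response_gfp": asdict(resp_g),
        "response_length": asdict(resp_m),
        "noise": asdict(noise),
    }
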