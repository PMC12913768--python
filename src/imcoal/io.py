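"""File formats: MSMC2 rate tables, estimate files, VCF, TMRCA tables,
pipeline configuration.

Unit conventions on disk follow the upstream tools: MSMC2 ``.final.txt``
tables are mutation-scaled (time in expected mutations per bp, coalescence
rates lambda such that N = 1/(2 mu lambda)); estimate files carry years and
per-generation rates.  All readers convert into the package's in-memory
convention (generations, per-generation hazards) using a ScalingConfig.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .coalsim import GenotypePanel, TmrcaSample
from .im_fit import FitConfig, IMTrajectory
from .im_model import LineageState, RateCurves, ScalingConfig, TimeGrid
from .traj_stats import PeriodCatalog

log = logging.getLogger("imcoal")

__all__ = [
    "read_msmc2_final",
    "write_msmc2_final",
    "write_estimate",
    "read_estimate",
    "read_vcf",
    "write_vcf",
    "write_tmrca_table",
    "read_tmrca_table",
    "PipelineConfig",
    "load_config",
    "save_config",
]

_MSMC2_CROSS_COLS = ["time_index", "left_time_boundary", "right_time_boundary",
                     "lambda_00", "lambda_01", "lambda_11"]
_MSMC2_WITHIN_COLS = ["time_index", "left_time_boundary",
                      "right_time_boundary", "lambda_00"]


def read_msmc2_final(path, scaling: ScalingConfig | None = None) -> RateCurves:
    """Read an MSMC2 ``.final.txt`` table into per-generation RateCurves.

    Accepts the cross-population dialect (lambda_00/lambda_01/lambda_11 =
    within-1 / cross / within-2) and the within-population dialect (a single
    lambda_00 column).  Times convert as t_gen = t_scaled / mu and hazards
    as h = lambda_scaled * mu (so that N = 1/(2 mu lambda)).  Malformed rows
    raise with their line number.
    """
    scaling = scaling or ScalingConfig()
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if header[:4] != _MSMC2_WITHIN_COLS[:4]:
            raise ValueError(
                f"{path}: unrecognized MSMC2 header {header!r}")
        cross = len(header) == 6
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != len(header):
                raise ValueError(f"{path}:{lineno}: expected "
                                 f"{len(header)} fields, got {len(parts)}")
            try:
                rows.append([float(x) for x in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    tab = np.asarray(rows)
    if tab.size == 0:
        raise ValueError(f"{path}: empty table")
    left = tab[:, 1]
    right = tab[:, 2]
    if np.any(left[1:] != right[:-1]):
        raise ValueError(f"{path}: time boundaries are not contiguous")
    boundaries = np.concatenate([left, [right[-1]]]) / scaling.mu
    if boundaries[0] <= 0:
        boundaries[0] = 0.0 if boundaries.size > 1 else boundaries[0]
    grid = TimeGrid(boundaries if boundaries[0] > 0
                    else np.concatenate([[0.0], boundaries[1:]]))
    lam = tab[:, 3:] * scaling.mu
    if cross:
        return RateCurves(grid=grid, lambda_11=lam[:, 0], lambda_12=lam[:, 1],
                          lambda_22=lam[:, 2], units="per_generation")
    return RateCurves(grid=grid, lambda_11=lam[:, 0], units="per_generation")


def write_msmc2_final(rates: RateCurves, path,
                      scaling: ScalingConfig | None = None) -> None:
    """Write RateCurves as an MSMC2 ``.final.txt`` table (mutation-scaled)."""
    scaling = scaling or ScalingConfig()
    if rates.units != "per_generation":
        raise ValueError("expected per-generation rates")
    b = rates.grid.boundaries * scaling.mu
    cross = rates.lambda_12 is not None and rates.lambda_22 is not None
    cols = _MSMC2_CROSS_COLS if cross else _MSMC2_WITHIN_COLS
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for k in range(rates.grid.n_intervals):
            lam = [rates.lambda_11[k] / scaling.mu]
            if cross:
                lam += [rates.lambda_12[k] / scaling.mu,
                        rates.lambda_22[k] / scaling.mu]
            fields = [str(k), repr(float(b[k])), repr(float(b[k + 1]))]
            fields += [repr(float(x)) for x in lam]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Estimate files (fitted trajectories)
# ---------------------------------------------------------------------------

def write_estimate(traj: IMTrajectory, path,
                   scaling: ScalingConfig | None = None) -> None:
    """Write a fitted trajectory as a tab-separated estimate table.

    Columns: time (years, left interval boundary), m, M (at the left
    boundary), im_N1, im_N2.  A leading comment line records the right
    boundary of the final interval so the grid round-trips losslessly.
    """
    scaling = scaling or ScalingConfig()
    if traj.grid.n_intervals == 0:
        raise ValueError("empty trajectory")
    b_years = traj.grid.boundaries * scaling.g
    with open(path, "w") as fh:
        fh.write(f"# final_time_years={float(b_years[-1])!r}\n")
        fh.write("time\tm\tM\tim_N1\tim_N2\n")
        for k in range(traj.grid.n_intervals):
            fh.write(f"{float(b_years[k])!r}\t{float(traj.m[k])!r}\t"
                     f"{float(traj.M[k])!r}\t{float(traj.im_N1[k])!r}\t"
                     f"{float(traj.im_N2[k])!r}\n")


def read_estimate(path, scaling: ScalingConfig | None = None) -> IMTrajectory:
    """Read an estimate table back into an IMTrajectory."""
    scaling = scaling or ScalingConfig()
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# final_time_years="):
            raise ValueError(f"{path}: missing final-time header")
        final_years = float(first.split("=", 1)[1])
        tab = pd.read_csv(fh, sep="\t")
    required = ["time", "m", "M", "im_N1", "im_N2"]
    if list(tab.columns) != required:
        raise ValueError(f"{path}: expected columns {required}")
    b_years = np.concatenate([tab["time"].to_numpy(), [final_years]])
    grid = TimeGrid(b_years / scaling.g)
    m = tab["m"].to_numpy()
    from .im_model import cumulative_migration
    M = cumulative_migration(m, grid)
    return IMTrajectory(grid=grid, m=m, M=M,
                        im_N1=tab["im_N1"].to_numpy(),
                        im_N2=tab["im_N2"].to_numpy())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, regions: dict[str, str] | None = None) -> GenotypePanel:
    """Read biallelic GT records from a VCF into a GenotypePanel.

    Multiallelic and GT-less records are skipped (a count is logged);
    missing genotypes map to -1.  ``regions`` optionally maps sample name to
    region label (default: one region "all").
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, positions, rows = [], [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or var.gt_types is None:
            skipped += 1
            continue
        # genotype dosage: cyvcf2 gt_types: 0=hom ref,1=het,2=unknown,3=hom alt
        gts = var.genotype.array()
        if gts is None:
            skipped += 1
            continue
        alleles = gts[:, :2]
        miss = (alleles < 0).any(axis=1)
        dosage = np.where(miss, -1, alleles.clip(0).sum(axis=1)).astype(np.int8)
        chroms.append(var.CHROM)
        positions.append(var.POS)
        rows.append(dosage)
    vcf.close()
    if skipped:
        log.info("read_vcf: skipped %d multiallelic/GT-less records", skipped)
    if not rows:
        raise ValueError(f"{path}: no usable biallelic GT records")
    region_labels = np.array([
        (regions or {}).get(s, "all") for s in samples])
    return GenotypePanel(
        samples=samples, regions=region_labels,
        chroms=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        genotypes=np.vstack(rows),
    )


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write a GenotypePanel as a minimal GT-only VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(panel.chroms):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for k in range(panel.n_sites):
            gts = "\t".join(code[int(g)] for g in panel.genotypes[k])
            fh.write(f"{panel.chroms[k]}\t{panel.positions[k]}\t.\tA\tT\t.\t"
                     f"PASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# TMRCA tables
# ---------------------------------------------------------------------------

def write_tmrca_table(samples: TmrcaSample, path) -> None:
    """Tab-separated TMRCA draws: time, censored, block, start state."""
    df = pd.DataFrame({
        "time_generations": samples.times,
        "censored": samples.censored.astype(int),
        "block": samples.block,
    })
    with open(path, "w") as fh:
        fh.write(f"# start={samples.start.name} seed={samples.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tmrca_table(path) -> TmrcaSample:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        meta = dict(kv.split("=") for kv in first.lstrip("# ").split())
        df = pd.read_csv(fh, sep="\t")
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    return TmrcaSample(
        times=df["time_generations"].to_numpy(),
        censored=df["censored"].to_numpy().astype(bool),
        start=LineageState[meta["start"]],
        block=df["block"].to_numpy(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Bundle of all tunables, YAML round-trippable."""

    scaling: ScalingConfig = field(default_factory=ScalingConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    periods: PeriodCatalog = field(default_factory=PeriodCatalog)
    grid_n_boundaries: int = 42
    grid_tmin: float = 1000.0
    grid_tmax: float = 5e5
    n_draws: int = 1_000_000
    seed: int = 0

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid.log_spaced(self.grid_n_boundaries, self.grid_tmin,
                                   self.grid_tmax)

    def to_dict(self) -> dict:
        d = {
            "scaling": asdict(self.scaling),
            "fit": {**asdict(self.fit),
                    "N_bounds": list(self.fit.N_bounds),
                    "m_bounds": list(self.fit.m_bounds)},
            "periods": {k: list(v) for k, v in self.periods.periods.items()},
            "grid_n_boundaries": self.grid_n_boundaries,
            "grid_tmin": self.grid_tmin,
            "grid_tmax": self.grid_tmax,
            "n_draws": self.n_draws,
            "seed": self.seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        fit = dict(d.get("fit", {}))
        if "N_bounds" in fit:
            fit["N_bounds"] = tuple(fit["N_bounds"])
        if "m_bounds" in fit:
            fit["m_bounds"] = tuple(fit["m_bounds"])
        return cls(
            scaling=ScalingConfig(**d.get("scaling", {})),
            fit=FitConfig(**fit),
            periods=PeriodCatalog({k: tuple(v) for k, v in
                                   d.get("periods", PeriodCatalog().periods
                                         ).items()}),
            grid_n_boundaries=d.get("grid_n_boundaries", 40),
            grid_tmin=d.get("grid_tmin", 1000.0),
            grid_tmax=d.get("grid_tmax", 5e5),
            n_draws=d.get("n_draws", 1_000_000),
            seed=d.get("seed", 0),
        )


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))
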