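"""Serialization: the delimited genotype dialect, VCF import, and tables.

The native genotype format is a tab-separated text table: one metadata
header line (``#`` + JSON), then one row per individual with its id
followed by two 0/1 columns per locus (homolog 1, homolog 2).  Trait
architectures and recombination maps are written as delimited tables
with the same JSON metadata header, so a whole synthetic study round-
trips through plain text.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .founder_synth import RecombinationMap
from .genome_core import OBSERVED, Population, TraitArchitecture

logger = logging.getLogger(__name__)

_HEADER_PREFIX = "#rrsim "


def _write_header(fh, meta: dict) -> None:
    fh.write(_HEADER_PREFIX + json.dumps(meta) + "\n")


def _read_header(path: Path) -> dict:
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith(_HEADER_PREFIX):
        return {}
    return json.loads(first[len(_HEADER_PREFIX):])


def write_genotypes(pop: Population, path: str | Path) -> None:
    """Write a population in the delimited genotype dialect."""
    path = Path(path)
    meta = dict(
        scope=pop.scope,
        pool_label=pop.pool_label,
        homozygous=pop.homozygous,
        n_loci=pop.n_loci,
    )
    flat = pop.genotypes.reshape(pop.n, -1)  # locus-major: (h1, h2) per locus
    with open(path, "w") as fh:
        _write_header(fh, meta)
        for i, pid in enumerate(pop.ids):
            fh.write(pid + "\t" + "\t".join(map(str, flat[i])) + "\n")


def read_genotypes(path: str | Path) -> Population:
    """Read a population written by :func:`write_genotypes`."""
    path = Path(path)
    meta = _read_header(path)
    ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append(np.array(parts[1:], dtype=np.int8))
    if not rows:
        raise ValueError(f"no genotype rows in {path}")
    flat = np.stack(rows)
    if flat.shape[1] % 2:
        raise ValueError("genotype table must have two columns per locus")
    geno = flat.reshape(flat.shape[0], flat.shape[1] // 2, 2)
    return Population(
        genotypes=geno,
        ids=ids,
        scope=meta.get("scope", OBSERVED),
        pool_label=meta.get("pool_label"),
        homozygous=bool(meta.get("homozygous", False)),
    )


def read_vcf(path: str | Path, rng: np.random.Generator | None = None) -> Population:
    """Import a VCF of biallelic diploid SNPs as an observed-scope population.

    Multi-allelic or non-diploid records are skipped with a warning.
    Unphased heterozygotes get a uniformly random phase (seeded via
    ``rng``), so the import is deterministic for a fixed generator.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    rng = rng or np.random.default_rng(0)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            skipped += 1
            continue
        gts = variant.genotypes  # [h1, h2, phased] per sample
        if any(len(g) != 3 or g[0] < 0 or g[1] < 0 for g in gts):
            skipped += 1
            continue
        col = np.empty((len(samples), 2), dtype=np.int8)
        for i, (h1, h2, phased) in enumerate(gts):
            if not phased and h1 != h2 and rng.integers(2):
                h1, h2 = h2, h1
            col[i] = (h1, h2)
        columns.append(col)
    if skipped:
        warnings.warn(f"skipped {skipped} multi-allelic/incomplete VCF records", stacklevel=2)
    if not columns:
        raise ValueError(f"no usable biallelic diploid records in {path}")
    geno = np.stack(columns, axis=1)  # (N, L, 2) of REF(0)/ALT(1) codes
    # recode per locus so 1 = major allele
    freq1 = geno.mean(axis=(0, 2))
    flip = freq1 < 0.5
    geno[:, flip, :] = 1 - geno[:, flip, :]
    return Population(genotypes=geno, ids=samples, scope=OBSERVED)


def import_genotypes(path: str | Path, fmt: str = "auto") -> Population:
    """Dispatch genotype import by format (``vcf`` or ``table``)."""
    path = Path(path)
    if fmt == "auto":
        fmt = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "table"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "table":
        return read_genotypes(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_architecture(arch: TraitArchitecture, path: str | Path) -> None:
    """Serialize an architecture as a full-genome effects table."""
    a_full, b_full = arch.full_vectors()
    observed = np.zeros(arch.n_full, dtype=int)
    observed[arch.observed_index_map] = 1
    a_obs = np.full(arch.n_full, np.nan)
    b_obs = np.full(arch.n_full, np.nan)
    a_obs[arch.observed_index_map] = arch.additive_obs
    b_obs[arch.observed_index_map] = arch.dominance_obs
    df = pd.DataFrame(
        {
            "locus": np.arange(arch.n_full),
            "observed": observed,
            "additive_full": a_full,
            "dominance_full": b_full,
            "additive_obs": a_obs,
            "dominance_obs": b_obs,
        }
    )
    with open(path, "w") as fh:
        _write_header(fh, dict(n_observed=arch.n_observed, n_full=arch.n_full))
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_architecture(path: str | Path) -> TraitArchitecture:
    df = pd.read_csv(path, sep="\t", comment="#", na_values="NA", float_precision="round_trip")
    obs_mask = df["observed"].to_numpy(dtype=bool)
    index_map = np.flatnonzero(obs_mask)
    return TraitArchitecture(
        additive_obs=df.loc[obs_mask, "additive_obs"].to_numpy(),
        dominance_obs=df.loc[obs_mask, "dominance_obs"].to_numpy(),
        additive_hidden=df.loc[~obs_mask, "additive_full"].to_numpy(),
        dominance_hidden=df.loc[~obs_mask, "dominance_full"].to_numpy(),
        observed_index_map=index_map,
        additive_obs_full=df.loc[obs_mask, "additive_full"].to_numpy(),
        dominance_obs_full=df.loc[obs_mask, "dominance_full"].to_numpy(),
    )


def write_recomb_map(rmap: RecombinationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        _write_header(fh, dict(n_obs=rmap.r_obs.size + 1, n_full=rmap.r_full.size + 1))
        fh.write("interval\tscope\trate\n")
        for j, r in enumerate(rmap.r_obs):
            fh.write(f"{j}\tobserved\t{float(r)!r}\n")
        for j, r in enumerate(rmap.r_full):
            fh.write(f"{j}\tfull\t{float(r)!r}\n")


def read_recomb_map(path: str | Path) -> RecombinationMap:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    return RecombinationMap(
        r_obs=df.loc[df["scope"] == "observed", "rate"].to_numpy(),
        r_full=df.loc[df["scope"] == "full", "rate"].to_numpy(),
    )


def write_testcross_matrix(matrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.row_ids, columns=matrix.col_ids)
    with open(path, "w") as fh:
        _write_header(fh, dict(predictor_kind=matrix.predictor_kind))
        df.to_csv(fh, sep="\t")
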