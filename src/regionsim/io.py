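"""Standard-format export/import and synthetic validation data.

Populations and case/control panels export to VCF 4.2 on a single
pseudo-contig: the continuous [0, 1) map positions become 1-based
integer coordinates via round(pos * 100000) + 1 (the region models
roughly 100 kb), with the exact real position kept in INFO/POS_REAL so
the infinite-sites coordinates survive a round trip.  Phenotypes and
affection status travel in a sidecar TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import FixationLog, MutationTable, PopulationState, SimulationConfig
from .varcomp import SampleMatrix

__all__ = [
    "export_vcf",
    "import_vcf",
    "export_phenotypes",
    "write_manifest",
    "fixture_unlinked_markers",
    "read_empirical_mafs",
]

CONTIG = "region1"
REGION_BP = 100_000


def _integer_positions(real_positions: np.ndarray) -> np.ndarray:
    """1-based bp coordinates; collisions resolved by +1 nudging."""
    raw = np.round(np.asarray(real_positions) * REGION_BP).astype(np.int64) + 1
    order = np.argsort(raw, kind="stable")
    out = raw.copy()
    last = -1
    for i in order:
        if out[i] <= last:
            out[i] = last + 1
        last = out[i]
    return out


def export_vcf(pop_or_matrix, path, phased: bool | None = None) -> None:
    """Write a population (phased GT) or dosage matrix (unphased) as VCF 4.2.

    INFO fields: EFFECT (trait effect), CAUSAL (flag), ORIGIN_GEN,
    POS_REAL.  An empty variant set produces a valid header-only file.
    """
    if isinstance(pop_or_matrix, PopulationState):
        pop = pop_or_matrix
        positions = pop.mutations.positions
        effects = pop.mutations.effects
        origins = pop.mutations.origins
        occ = pop.occupancy
        n_ind = pop.n_diploids
        phased = True if phased is None else phased
        gt = lambda i, j: (  # noqa: E731
            f"{occ[2 * i, j]}|{occ[2 * i + 1, j]}"
            if phased
            else f"{min(occ[2 * i, j] + occ[2 * i + 1, j], 1)}/{1 if occ[2 * i, j] + occ[2 * i + 1, j] == 2 else 0}"
        )
    else:
        sm = pop_or_matrix
        positions = np.asarray(sm.site_position)
        effects = np.asarray(sm.site_effect)
        origins = np.zeros(len(positions), dtype=np.int64)
        dos = sm.dosages
        n_ind = dos.shape[0]
        phased = False

        def gt(i, j):
            d = dos[i, j]
            return "1/1" if d == 2 else ("0/1" if d == 1 else "0/0")

    order = np.argsort(positions, kind="stable")
    bp = _integer_positions(positions)
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=regionsim {__version__}",
        f"##contig=<ID={CONTIG},length={REGION_BP + len(positions) + 2}>",
        '##INFO=<ID=EFFECT,Number=1,Type=Float,Description="Trait effect size">',
        '##INFO=<ID=CAUSAL,Number=0,Type=Flag,Description="Site affects the trait">',
        '##INFO=<ID=ORIGIN_GEN,Number=1,Type=Integer,Description="Generation of origin">',
        '##INFO=<ID=POS_REAL,Number=1,Type=Float,Description="Continuous map position in [0,1)">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(f"ind{i}" for i in range(n_ind)),
    ]
    for j in order:
        info = f"EFFECT={effects[j]:.10g};ORIGIN_GEN={origins[j]};POS_REAL={positions[j]:.17g}"
        if effects[j] > 0:
            info = "CAUSAL;" + info
        row = [
            CONTIG,
            str(bp[j]),
            f"site{j}",
            "A",
            "T",
            ".",
            "PASS",
            info,
            "GT",
        ] + [gt(i, j) for i in range(n_ind)]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def import_vcf(path):
    """Read a regionsim VCF back into ``(occupancy, MutationTable)``.

    Phased genotypes preserve gamete identity; unphased ones are
    assigned arbitrarily within the diploid (dosage is preserved
    exactly either way).
    """
    positions, effects, origins, rows = [], [], [], []
    n_ind = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                n_ind = len(line.split("\t")) - 9
                continue
            fields = line.split("\t")
            info = dict(
                kv.split("=", 1) if "=" in kv else (kv, True)
                for kv in fields[7].split(";")
            )
            positions.append(float(info.get("POS_REAL", (int(fields[1]) - 1) / REGION_BP)))
            effects.append(float(info.get("EFFECT", 0.0)))
            origins.append(int(info.get("ORIGIN_GEN", 0)))
            alleles = []
            for g in fields[9:]:
                sep = "|" if "|" in g else "/"
                a, b = g.split(sep)
                alleles.extend([int(a), int(b)])
            rows.append(alleles)
    if n_ind is None:
        raise ValueError("missing #CHROM header line")
    table = MutationTable(positions, effects, origins)
    occ = (
        np.asarray(rows, dtype=np.uint8).T
        if rows
        else np.zeros((2 * n_ind, 0), dtype=np.uint8)
    )
    return occ, table


def export_phenotypes(phenotypes, path, status=None, genetic_values=None) -> None:
    """Sidecar TSV with per-individual phenotype (and optional extras)."""
    df = pd.DataFrame({"individual": [f"ind{i}" for i in range(len(phenotypes))]})
    df["phenotype"] = np.asarray(phenotypes)
    if genetic_values is not None:
        df["genetic_value"] = np.asarray(genetic_values)
    if status is not None:
        df["status"] = np.asarray(status)
    df.to_csv(path, sep="\t", index=False)


def write_manifest(path, config: SimulationConfig, extra: dict | None = None) -> None:
    """JSON manifest: resolved config, seed and software version."""
    doc = {
        "software": "regionsim",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def fixture_unlinked_markers(
    n_markers: int = 1000,
    n_individuals: int = 5000,
    lambda_: float = 0.1,
    rng: np.random.Generator | None = None,
    n_fix: int = 10_000,
) -> SampleMatrix:
    """Synthetic unlinked HWE markers with a purely additive trait.

    Marker frequencies follow the neutral Wright-Fisher density
    (proportional to 1/q, truncated to [1/(2 N), 1 - 1/(2 N)] with
    N = ``n_fix``), effects are Exponential(mean ``lambda_``), and
    genotypes are Binomial(2, q) per individual.  The additive genetic
    value is the dosage-weighted effect sum; phenotypes equal genetic
    values (no noise).  Used to validate the regression-based variance
    estimates against the classical per-site formula 2 p q alpha^2.
    """
    rng = np.random.default_rng() if rng is None else rng
    lo, hi = 1.0 / (2.0 * n_fix), 1.0 - 1.0 / (2.0 * n_fix)
    # inverse-CDF sampling of density 1/q on [lo, hi]
    q = lo * (hi / lo) ** rng.random(n_markers)
    alpha = rng.exponential(lambda_, n_markers)
    dosages = rng.binomial(2, q, size=(n_individuals, n_markers)).astype(np.int8)
    g = dosages @ alpha
    return SampleMatrix(
        dosages=dosages,
        site_freq=q,
        site_effect=alpha,
        phenotypes=g,
        genetic_values=g,
        site_position=np.linspace(0, 1, n_markers, endpoint=False),
    )


def read_empirical_mafs(path) -> np.ndarray:
    """Headerless single-column TSV of empirical GWAS top-hit MAFs."""
    vals = pd.read_csv(path, sep="\t", header=None)[0].to_numpy(dtype=float)
    if np.any((vals < 0) | (vals > 0.5)):
        raise ValueError("MAFs must lie in [0, 0.5]")
    return vals
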