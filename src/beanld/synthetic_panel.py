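"""Synthetic inbred SNP panels with planted structure, kinship and LD.

The generator emulates a diversity panel of predominantly homozygous
(inbred) common-bean accessions: two strongly diverged gene pools plus a
handful of inter-pool recombinant inbred lines (RILs), family clusters
within pools (few founder haplotypes), 11 chromosomes with non-uniform SNP
placement, distance-decaying intra-chromosomal LD, sparse heterozygous
error calls, and entry-wise missingness.

Model
-----
* Pool divergence is Balding-Nichols: ancestral allele frequency
  ``p ~ Uniform(0.1, 0.9)`` per locus, pool frequency
  ``p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F)`` with differentiation ``F``.
* Each pool holds ``n_founder_haplotypes`` binary founder haplotypes per
  chromosome, drawn locus-wise from the pool frequency.
* An inbred line's chromosome is a mosaic of its pool's founders: between
  consecutive loci the founder is redrawn uniformly with probability
  ``1 - exp(-recomb_rate_per_bp * gap_bp)``. Genotype = doubled haplotype,
  so truth dosages are {0, 2}.
* RILs cross one parent line from each of the first two pools, then self
  for ``selfing_generations`` meioses with the same crossover process;
  residual heterozygous loci are fixed to a random parental allele.
* Noise: heterozygous error calls (dosage 1) then missingness, each an
  independent Bernoulli per matrix entry.

Everything is deterministic given ``PanelSpec.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genotype_io import MISSING, GenotypeMatrix, build_locus_table

#: Chromosome lengths (bp) of the 11 common-bean pseudomolecules Pv01-Pv11.
DEFAULT_CHROM_LENGTHS_BP: tuple[int, ...] = (
    52_180_000,
    49_030_000,
    52_210_000,
    45_790_000,
    40_230_000,
    31_970_000,
    51_690_000,
    59_630_000,
    37_390_000,
    43_210_000,
    50_200_000,
)

RIL_LABEL = "RIL"


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of one synthetic panel.

    Defaults emulate the study panel this package targets: 180 accessions
    in two gene pools (139 + 27 pure-pool lines plus 14 inter-pool F10
    RILs), 11 chromosomes at their reference lengths, moderate divergence
    (F = 0.3), 8 founder haplotypes per pool (families / narrow breeding
    base), recombination scaled so corrected LD decays on the Mb scale,
    sparse heterozygous errors and ~8% missing calls.
    """

    n_pools: int = 2
    lines_per_pool: tuple[int, ...] = (139, 27)
    n_ril: int = 14
    divergence_F: float = 0.3
    n_founder_haplotypes: int = 8
    chrom_lengths_bp: tuple[int, ...] = DEFAULT_CHROM_LENGTHS_BP
    loci_per_chrom: tuple[int, ...] = (40,) * 11
    recomb_rate_per_bp: float = 1e-6
    selfing_generations: int = 9
    missing_rate: float = 0.08
    het_error_rate: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        if self.n_pools < 1:
            raise ValidationError("n_pools must be >= 1")
        if len(self.lines_per_pool) != self.n_pools:
            raise ValidationError("lines_per_pool length must equal n_pools")
        if any(c < 1 for c in self.lines_per_pool):
            raise ValidationError("each pool needs at least one line")
        if not 0.0 < self.divergence_F < 1.0:
            raise ValidationError("divergence_F must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.het_error_rate < 1.0:
            raise ValidationError("het_error_rate must lie in [0, 1)")
        if len(self.chrom_lengths_bp) != len(self.loci_per_chrom):
            raise ValidationError(
                "chrom_lengths_bp and loci_per_chrom must have equal length"
            )
        if len(self.chrom_lengths_bp) < 1:
            raise ValidationError("at least one chromosome required")
        for length, m in zip(self.chrom_lengths_bp, self.loci_per_chrom):
            if m < 1 or length < 1:
                raise ValidationError("chromosome lengths and loci must be >= 1")
            if m > length:
                raise ValidationError(
                    f"{m} loci do not fit in a {length} bp chromosome"
                )
        if self.n_ril > 0 and self.n_pools < 2:
            raise ValidationError("RILs require at least two pools")
        if self.n_founder_haplotypes < 1:
            raise ValidationError("need at least one founder haplotype")
        if self.selfing_generations < 0:
            raise ValidationError("selfing_generations must be >= 0")
        if self.recomb_rate_per_bp < 0:
            raise ValidationError("recomb_rate_per_bp must be >= 0")

    @property
    def n_lines(self) -> int:
        return int(sum(self.lines_per_pool)) + self.n_ril

    @property
    def n_loci(self) -> int:
        return int(sum(self.loci_per_chrom))


@dataclass
class PanelTruth:
    """Ground truth of a simulated panel.

    ``pool_label`` marks each line with its pool name (``"RIL"`` for
    inter-pool lines). ``founder_mosaic`` stores, for pure-pool lines, the
    within-pool founder index underlying each locus (``-1`` for RILs).
    ``ril_parents`` maps each RIL row index to its two parent row indices.
    """

    pool_label: list[str]
    ancestral_freq: np.ndarray
    pool_freq: np.ndarray  # (n_pools, n_loci)
    founder_mosaic: np.ndarray  # (n_lines, n_loci) int16
    ril_parents: dict[int, tuple[int, int]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pool_label": self.pool_label,
            "ancestral_freq": self.ancestral_freq.tolist(),
            "pool_freq": self.pool_freq.tolist(),
            "founder_mosaic": self.founder_mosaic.tolist(),
            "ril_parents": {str(k): list(v) for k, v in self.ril_parents.items()},
        }
        Path(path).write_text(json.dumps(payload))


def _pool_name(k: int) -> str:
    return f"pool{k + 1}"


def _mosaic_indices(
    rng: np.random.Generator, n_lines: int, p_switch: np.ndarray, n_founders: int
) -> np.ndarray:
    """Founder index per (line, locus) under the Markov switching process.

    ``p_switch[j]`` is the probability of redrawing the founder between
    locus ``j-1`` and ``j`` (entry 0 is ignored; the first founder is
    always drawn).
    """
    m = len(p_switch)
    choices = rng.integers(0, n_founders, size=(n_lines, m))
    switch = rng.random((n_lines, m)) < p_switch[None, :]
    switch[:, 0] = True
    cols = np.arange(m)
    last_switch = np.maximum.accumulate(np.where(switch, cols, -1), axis=1)
    return np.take_along_axis(choices, last_switch, axis=1)


def _gamete(
    rng: np.random.Generator,
    h1: np.ndarray,
    h2: np.ndarray,
    p_switch: np.ndarray,
) -> np.ndarray:
    """One meiotic product of a haplotype pair (single chromosome)."""
    pick = _mosaic_indices(rng, 1, p_switch, 2)[0]
    return np.where(pick == 0, h1, h2)


def simulate_panel(
    spec: PanelSpec,
) -> tuple[GenotypeMatrix, pd.DataFrame, PanelTruth]:
    """Simulate one panel; see the module docstring for the model."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_chrom = len(spec.chrom_lengths_bp)
    m_total = spec.n_loci
    n_lines = spec.n_lines

    # locus map: positions uniform without replacement, sorted, 1-based
    chrom_names: list[str] = []
    positions = np.empty(m_total, dtype=np.int64)
    chrom_slices: list[slice] = []
    start = 0
    for c in range(n_chrom):
        m = spec.loci_per_chrom[c]
        pos = np.sort(
            rng.choice(spec.chrom_lengths_bp[c], size=m, replace=False) + 1
        )
        sl = slice(start, start + m)
        positions[sl] = pos
        chrom_names += [f"Pv{c + 1:02d}"] * m
        chrom_slices.append(sl)
        start += m

    p_anc = rng.uniform(0.1, 0.9, size=m_total)
    F = spec.divergence_F
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    pool_freq = np.empty((spec.n_pools, m_total))
    for k in range(spec.n_pools):
        pool_freq[k] = rng.beta(a, b)

    # founder haplotypes per pool per chromosome
    K = spec.n_founder_haplotypes
    founders = np.empty((spec.n_pools, K, m_total), dtype=np.int8)
    for k in range(spec.n_pools):
        founders[k] = (rng.random((K, m_total)) < pool_freq[k][None, :]).astype(
            np.int8
        )

    p_switch_per_chrom: list[np.ndarray] = []
    for c, sl in enumerate(chrom_slices):
        gaps = np.diff(positions[sl], prepend=positions[sl][0])
        p_switch = 1.0 - np.exp(-spec.recomb_rate_per_bp * gaps)
        p_switch[0] = 0.0
        p_switch_per_chrom.append(p_switch)

    haplotypes = np.empty((n_lines, m_total), dtype=np.int8)
    founder_mosaic = np.full((n_lines, m_total), -1, dtype=np.int16)
    pool_label: list[str] = []
    row = 0
    pool_rows: list[np.ndarray] = []
    for k in range(spec.n_pools):
        nk = spec.lines_per_pool[k]
        rows_k = np.arange(row, row + nk)
        pool_rows.append(rows_k)
        pool_label += [_pool_name(k)] * nk
        for c, sl in enumerate(chrom_slices):
            idx = _mosaic_indices(rng, nk, p_switch_per_chrom[c], K)
            founder_mosaic[np.ix_(rows_k, range(sl.start, sl.stop))] = idx
        idx_all = founder_mosaic[rows_k]
        haplotypes[rows_k] = founders[k][
            idx_all, np.arange(m_total)[None, :]
        ].astype(np.int8)
        row += nk

    ril_parents: dict[int, tuple[int, int]] = {}
    for r in range(spec.n_ril):
        i_ril = row + r
        p0 = int(rng.integers(0, len(pool_rows[0])))
        p1 = int(rng.integers(0, len(pool_rows[1])))
        parent0 = int(pool_rows[0][p0])
        parent1 = int(pool_rows[1][p1])
        ril_parents[i_ril] = (parent0, parent1)
        pool_label.append(RIL_LABEL)
        h1 = haplotypes[parent0].copy()
        h2 = haplotypes[parent1].copy()
        for _ in range(spec.selfing_generations):
            new1 = np.empty(m_total, dtype=np.int8)
            new2 = np.empty(m_total, dtype=np.int8)
            for c, sl in enumerate(chrom_slices):
                ps = p_switch_per_chrom[c]
                new1[sl] = _gamete(rng, h1[sl], h2[sl], ps)
                new2[sl] = _gamete(rng, h1[sl], h2[sl], ps)
            h1, h2 = new1, new2
        het = h1 != h2
        if het.any():
            pick2 = rng.random(int(het.sum())) < 0.5
            fixed = np.where(pick2, h2[het], h1[het])
            h1[het] = fixed
            h2[het] = fixed
        haplotypes[i_ril] = h1

    values = (2 * haplotypes).astype(np.int8)

    if spec.het_error_rate > 0:
        het_mask = rng.random(values.shape) < spec.het_error_rate
        values[het_mask] = 1
    if spec.missing_rate > 0:
        miss_mask = rng.random(values.shape) < spec.missing_rate
        values[miss_mask] = MISSING

    ids = []
    counter: dict[str, int] = {}
    for lab in pool_label:
        counter[lab] = counter.get(lab, 0) + 1
        ids.append(f"{lab}_{counter[lab]:03d}")
    G = GenotypeMatrix(values, ids)

    ref = np.full(m_total, "A")
    alt = np.full(m_total, "G")
    L = build_locus_table(chrom_names, positions, ref, alt, values)
    truth = PanelTruth(
        pool_label=pool_label,
        ancestral_freq=p_anc,
        pool_freq=pool_freq,
        founder_mosaic=founder_mosaic,
        ril_parents=ril_parents,
    )
    return G, L, truth


def unlinked_pairs_spec(
    n_pairs: int,
    lines_per_pool: tuple[int, ...],
    divergence_F: float,
    *,
    n_founder_haplotypes: int = 64,
    n_ril: int = 0,
    seed: int = 0,
) -> PanelSpec:
    """A panel of ``2 * n_pairs`` unlinked loci (one locus per chromosome).

    Convenience for null experiments on locus pairs that carry no physical
    linkage: every locus sits alone on its own chromosome, so any LD is
    attributable to structure, kinship or sampling noise.
    """
    m = 2 * n_pairs
    return PanelSpec(
        n_pools=len(lines_per_pool),
        lines_per_pool=tuple(lines_per_pool),
        n_ril=n_ril,
        divergence_F=divergence_F,
        n_founder_haplotypes=n_founder_haplotypes,
        chrom_lengths_bp=(1_000_000,) * m,
        loci_per_chrom=(1,) * m,
        recomb_rate_per_bp=1e-6,
        selfing_generations=6,
        missing_rate=0.0,
        het_error_rate=0.0,
        seed=seed,
    )


def spec_to_dict(spec: PanelSpec) -> dict:
    d = asdict(spec)
    d["lines_per_pool"] = list(spec.lines_per_pool)
    d["chrom_lengths_bp"] = list(spec.chrom_lengths_bp)
    d["loci_per_chrom"] = list(spec.loci_per_chrom)
    return d


def spec_from_dict(d: dict) -> PanelSpec:
    d = dict(d)
    for key in ("lines_per_pool", "chrom_lengths_bp", "loci_per_chrom"):
        if key in d:
            d[key] = tuple(d[key])
    return PanelSpec(**d)
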