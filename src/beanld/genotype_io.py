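"""Genotype containers and I/O for VCF and plain TSV dosage matrices.

The canonical in-memory representation is a :class:`GenotypeMatrix`
(accessions x loci ALT-allele dosage codes ``{0, 1, 2}`` with ``-1`` as the
missing sentinel) paired with a :class:`pandas.DataFrame` locus table holding
``chrom``, ``pos`` (1-based bp), ``ref``, ``alt``, ``maf`` and
``missing_rate`` per locus.

Dosage counts the ALT allele, not the minor allele; every LD statistic in
this package is invariant under the flip ``x -> 2 - x``, so the coding is
stable under filtering while MAF is recomputed on the fly.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1

LOCUS_COLUMNS = ["chrom", "pos", "ref", "alt", "maf", "missing_rate"]


@dataclass
class GenotypeMatrix:
    """Accessions x loci integer dosage matrix.

    Parameters
    ----------
    values
        ``(n_accessions, n_loci)`` integer array with codes in ``{0, 1, 2}``
        and :data:`MISSING` (``-1``) for no-calls.
    accession_ids
        Unique accession names, one per row.
    """

    values: np.ndarray
    accession_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValidationError("genotype values must be a 2-D array")
        self.accession_ids = [str(a) for a in self.accession_ids]
        if len(self.accession_ids) != self.values.shape[0]:
            raise ValidationError(
                f"{len(self.accession_ids)} accession ids for "
                f"{self.values.shape[0]} rows"
            )
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValidationError("accession ids must be unique")
        bad = ~np.isin(self.values, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValidationError(
                f"invalid genotype codes {np.unique(self.values[bad])!r}"
            )

    @property
    def n_accessions(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def is_complete(self) -> bool:
        return not (self.values == MISSING).any()

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.values.copy(), list(self.accession_ids))

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset loci (columns), preserving order of ``index``."""
        return GenotypeMatrix(self.values[:, index], list(self.accession_ids))

    def take_accessions(self, index: np.ndarray) -> "GenotypeMatrix":
        ids = [self.accession_ids[i] for i in np.atleast_1d(index)]
        return GenotypeMatrix(self.values[np.atleast_1d(index), :], ids)


def compute_maf(values: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per locus from non-missing dosages.

    Loci with no calls at all get ``nan`` (they are dropped by any MAF
    filter with a positive threshold).
    """
    v = np.asarray(values)
    obs = v != MISSING
    n_obs = obs.sum(axis=0)
    alt = np.where(obs, v, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_alt = np.where(n_obs > 0, alt / (2.0 * np.maximum(n_obs, 1)), np.nan)
    return np.minimum(f_alt, 1.0 - f_alt)


def compute_missing_rate(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values)
    return (v == MISSING).mean(axis=0)


def build_locus_table(
    chrom, pos, ref, alt, values: np.ndarray | None = None
) -> pd.DataFrame:
    """Assemble a locus table; MAF/missing-rate from ``values`` if given."""
    n = len(pos)
    table = pd.DataFrame(
        {
            "chrom": pd.Series(chrom, dtype="string").astype(str),
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": pd.Series(ref, dtype="string").astype(str),
            "alt": pd.Series(alt, dtype="string").astype(str),
            "maf": compute_maf(values) if values is not None else np.full(n, np.nan),
            "missing_rate": compute_missing_rate(values)
            if values is not None
            else np.zeros(n),
        }
    )
    validate_locus_table(table)
    return table


def recompute_locus_stats(G: GenotypeMatrix, L: pd.DataFrame) -> pd.DataFrame:
    """Return ``L`` with ``maf``/``missing_rate`` recomputed from ``G``."""
    if len(L) != G.n_loci:
        raise ValidationError("locus table and genotype matrix disagree on loci")
    out = L.copy()
    out["maf"] = compute_maf(G.values)
    out["missing_rate"] = compute_missing_rate(G.values)
    return out


def validate_locus_table(L: pd.DataFrame) -> None:
    missing_cols = [c for c in ("chrom", "pos") if c not in L.columns]
    if missing_cols:
        raise ValidationError(f"locus table lacks columns {missing_cols}")
    for chrom, block in L.groupby("chrom", sort=False):
        p = block["pos"].to_numpy()
        if len(p) > 1 and not (np.diff(p) > 0).all():
            raise ValidationError(
                f"positions on {chrom} are not strictly increasing"
            )


def validate_consistent(G: GenotypeMatrix, L: pd.DataFrame) -> None:
    if G.n_loci != len(L):
        raise ValidationError(
            f"{G.n_loci} genotype columns but {len(L)} locus rows"
        )
    validate_locus_table(L)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a VCF (v4.2 subset, GT-only semantics) into dosage codes.

    Diploid GT maps ``0/0 -> 0``, ``0/1 | 1/0 -> 1``, ``1/1 -> 2``,
    ``./.`` or ``.`` -> missing; haploid ``0 -> 0``, ``1 -> 2``. Phased
    separators are treated as unphased. Non-biallelic or non-SNP records
    are skipped with a warning.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=True)
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise FormatError(f"{path}: no GT FORMAT declared in header")
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    seen: set[tuple[str, int]] = set()
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            logger.warning(
                "skipping non-biallelic-SNP record %s:%d", var.CHROM, var.POS
            )
            continue
        key = (var.CHROM, var.POS)
        if key in seen:
            raise FormatError(f"duplicated record at {var.CHROM}:{var.POS}")
        seen.add(key)
        # with gts012=True: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt)
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
    vcf.close()
    values = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    G = GenotypeMatrix(values, samples)
    L = build_locus_table(chroms, positions, refs, alts, values)
    return G, L


def write_vcf(G: GenotypeMatrix, L: pd.DataFrame, path: str | Path) -> None:
    """Write a GT-only VCF v4.2. Gzip transparently if path ends in .gz."""
    validate_consistent(G, L)
    path = str(path)
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in L["chrom"].unique():
            length = int(L.loc[L["chrom"] == chrom, "pos"].max()) if len(L) else 0
            fh.write(f"##contig=<ID={chrom},length={max(length + 1, 1)}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.accession_ids)
            + "\n"
        )
        for j, row in enumerate(L.itertuples(index=False)):
            calls = "\t".join(code_to_gt[int(c)] for c in G.values[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t.\tGT\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def read_tsv(path: str | Path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read the plain matrix dialect.

    Header row: ``chrom pos ref alt <accession ids...>``; one row per locus
    with dosage codes and ``NA`` for missing. Gzip transparent.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    fixed = ["chrom", "pos", "ref", "alt"]
    if header[:4] != fixed:
        raise FormatError(f"{path}: expected leading columns {fixed}")
    ids = header[4:]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicated accession id in header")
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise FormatError(f"{path}: {exc}") from exc
    df.columns = header  # undo pandas' duplicate-name mangling
    codes = df[ids].to_numpy(dtype=float)
    values = np.where(np.isnan(codes), MISSING, codes).astype(np.int8).T
    G = GenotypeMatrix(values, ids)
    L = build_locus_table(df["chrom"], df["pos"], df["ref"], df["alt"], values)
    return G, L


def write_tsv(G: GenotypeMatrix, L: pd.DataFrame, path: str | Path) -> None:
    validate_consistent(G, L)
    codes = pd.DataFrame(
        G.values.T, columns=G.accession_ids, dtype="object"
    ).mask(pd.DataFrame(G.values.T == MISSING, columns=G.accession_ids), "NA")
    df = pd.concat(
        [L[["chrom", "pos", "ref", "alt"]].reset_index(drop=True), codes],
        axis=1,
    )
    df.to_csv(path, sep="\t", index=False)
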