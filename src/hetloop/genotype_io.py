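"""Genotype, phenotype, covariate and gene-set I/O plus basic panel algebra.

Genotypes live in a :class:`GenotypeDataset`: subjects × SNPs minor-allele
counts (0/1/2, NaN for missing) together with the subject phenotype records
and the SNP map.  Two text formats are supported: a PLINK-style ``.ped`` /
``.map`` pair and a tab-delimited additive dosage table.  Genotypes are
expanded into signed allele-combination presence matrices
(:class:`ComboMatrix`), the unit on which the biclustering operates: each SNP
contributes three binary features (homozygous major, heterozygous, homozygous
minor), encoded +1 when the subject exhibits that combination and -1 when it
does not.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

COMBO_KINDS = ("hom_major", "het", "hom_minor")

SUBJECT_COLUMNS = ["subject_id", "status", "subtype", "arm_id"]
SNP_COLUMNS = ["snp_id", "chrom", "pos_bp", "allele_major", "allele_minor", "maf"]


class GenotypeFormatError(ValueError):
    """Raised on malformed genotype/phenotype input."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeDataset:
    """Subjects × SNPs minor-allele counts with phenotype labels and SNP map.

    ``calls[i, j]`` counts copies of the minor allele of SNP ``j`` carried by
    subject ``i`` (0, 1, 2) with ``NaN`` marking a missing call.
    """

    subjects: pd.DataFrame
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.subjects = self.subjects.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.float64)
        self.validate()

    # -- basic accessors ----------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.subjects["subject_id"].to_numpy()

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["snp_id"].to_numpy()

    def case_mask(self) -> np.ndarray:
        return (self.subjects["status"] == "case").to_numpy()

    def validate(self) -> None:
        if self.calls.shape != (len(self.subjects), len(self.snps)):
            raise GenotypeFormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.snps)} SNPs"
            )
        dup = self.subjects["subject_id"][self.subjects["subject_id"].duplicated()]
        if len(dup):
            raise GenotypeFormatError(f"duplicate subject ids: {sorted(set(dup))}")
        dup = self.snps["snp_id"][self.snps["snp_id"].duplicated()]
        if len(dup):
            raise GenotypeFormatError(f"duplicate snp ids: {sorted(set(dup))}")
        bad_status = set(self.subjects["status"]) - {"case", "control"}
        if bad_status:
            raise GenotypeFormatError(f"unknown status values: {sorted(bad_status)}")
        bad_subtype = set(self.subjects["subtype"]) - {"BDI", "BDII", "unknown"}
        if bad_subtype:
            raise GenotypeFormatError(f"unknown subtype values: {sorted(bad_subtype)}")
        typed_controls = self.subjects[
            (self.subjects["status"] == "control") & (self.subjects["subtype"] != "unknown")
        ]
        if len(typed_controls):
            raise GenotypeFormatError(
                "subtype labels are only allowed on cases; offending subjects: "
                f"{list(typed_controls['subject_id'])[:5]}"
            )
        if (self.snps["pos_bp"] < 1).any():
            raise GenotypeFormatError("pos_bp must be >= 1 (1-based positions)")
        with np.errstate(invalid="ignore"):
            out_of_range = np.nansum((self.calls < 0) | (self.calls > 2))
        if out_of_range:
            raise GenotypeFormatError("calls must lie in {0, 1, 2} or be missing")

    def computed_maf(self) -> np.ndarray:
        """Minor-allele frequency recomputed from the call matrix."""
        observed = ~np.isnan(self.calls)
        counts = np.nansum(self.calls, axis=0)
        denom = 2.0 * observed.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, counts / denom, np.nan)

    def subset_snps(self, keep: np.ndarray) -> "GenotypeDataset":
        return GenotypeDataset(
            subjects=self.subjects.copy(),
            snps=self.snps.iloc[np.asarray(keep)].reset_index(drop=True),
            calls=self.calls[:, np.asarray(keep)],
        )

    def subset_subjects(self, keep: np.ndarray) -> "GenotypeDataset":
        return GenotypeDataset(
            subjects=self.subjects.iloc[np.asarray(keep)].reset_index(drop=True),
            snps=self.snps.copy(),
            calls=self.calls[np.asarray(keep), :],
        )


@dataclass
class ComboMatrix:
    """Subjects × allele-combinations signed presence matrix.

    ``values`` entries are +1 (subject exhibits the combination), -1 (does
    not) or NaN (missing call).  For every subject and non-missing SNP exactly
    one of the three kinds per SNP is +1.
    """

    subject_ids: np.ndarray
    combos: pd.DataFrame  # columns: snp_id, kind
    values: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.combos = self.combos.reset_index(drop=True)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.subject_ids), len(self.combos)):
            raise ValueError("values shape does not match subject/combo lists")

    @property
    def combo_ids(self) -> np.ndarray:
        return (self.combos["snp_id"] + ":" + self.combos["kind"]).to_numpy()

    @property
    def snp_ids(self) -> np.ndarray:
        return self.combos["snp_id"].to_numpy()

    def restrict_subjects(self, idx: np.ndarray) -> "ComboMatrix":
        idx = np.asarray(idx)
        return ComboMatrix(self.subject_ids[idx], self.combos.copy(), self.values[idx])

    def restrict_combos(self, idx: np.ndarray) -> "ComboMatrix":
        idx = np.asarray(idx)
        return ComboMatrix(
            self.subject_ids.copy(),
            self.combos.iloc[idx].reset_index(drop=True),
            self.values[:, idx],
        )


@dataclass
class GeneAnnotation:
    """Mapping gene -> set of combo ids on the analysis panel."""

    gene_to_combos: dict
    unmatched_snps: set = field(default_factory=set)

    def genes(self) -> list:
        return sorted(self.gene_to_combos)


@dataclass
class PathwayCollection:
    """Pathway -> gene-set mapping over a declared gene universe."""

    pathways: dict
    universe: set

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            extra = set(genes) - self.universe
            if extra:
                raise ValueError(
                    f"pathway {name!r} references genes outside the universe: "
                    f"{sorted(extra)[:5]}"
                )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _default_subjects(subject_ids: Sequence[str], statuses: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": list(subject_ids),
            "status": list(statuses),
            "subtype": ["unknown"] * len(subject_ids),
            "arm_id": [""] * len(subject_ids),
        }
    )


def read_phenotypes(path: Path) -> pd.DataFrame:
    """Read a tab-delimited phenotype table keyed by subject_id."""
    tbl = pd.read_csv(path, sep="\t", dtype=str)
    if "subject_id" not in tbl.columns or "status" not in tbl.columns:
        raise GenotypeFormatError(
            f"{path}: phenotype table needs 'subject_id' and 'status' columns"
        )
    if "subtype" not in tbl.columns:
        tbl["subtype"] = "unknown"
    if "arm_id" not in tbl.columns:
        tbl["arm_id"] = ""
    tbl["subtype"] = tbl["subtype"].fillna("unknown")
    tbl["arm_id"] = tbl["arm_id"].fillna("")
    return tbl[SUBJECT_COLUMNS]


def read_covariate_table(path: Path) -> pd.DataFrame:
    """Read a tab-delimited covariate table; index subject_id, float columns."""
    tbl = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in tbl.columns:
        raise GenotypeFormatError(f"{path}: covariate table needs a 'subject_id' column")
    tbl = tbl.set_index("subject_id")
    return tbl.astype(float)


def _merge_phenotypes(
    subjects: pd.DataFrame, phenotype_path: Path | None
) -> pd.DataFrame:
    if phenotype_path is None:
        return subjects
    pheno = read_phenotypes(phenotype_path)
    geno_ids = set(subjects["subject_id"])
    pheno_ids = set(pheno["subject_id"])
    if geno_ids != pheno_ids:
        missing = sorted(geno_ids - pheno_ids)
        extra = sorted(pheno_ids - geno_ids)
        raise GenotypeFormatError(
            "phenotype/genotype subject mismatch; "
            f"genotyped-but-unphenotyped: {missing[:10]}, "
            f"phenotyped-but-ungenotyped: {extra[:10]}"
        )
    merged = subjects[["subject_id"]].merge(pheno, on="subject_id", how="left")
    return merged[SUBJECT_COLUMNS]


def read_genotypes(
    genotype_path: Path,
    phenotype_path: Path | None = None,
    format: str = "ped_map",
) -> GenotypeDataset:
    """Load genotypes plus phenotype labels into a validated dataset.

    ``format='ped_map'`` expects ``genotype_path`` to be the ``.ped`` file
    with a sibling ``.map``; case/control status comes from the PHENO column
    (1=control, 2=case) and may be refined (subtype, arm) by the phenotype
    table.  ``format='dosage_table'`` expects a tab-delimited table with a
    ``subject_id`` column and one 0/1/2/NA column per SNP; status must come
    from the phenotype table.  The minor allele per SNP is the less frequent
    allele in the loaded sample, ties broken lexicographically.
    """
    genotype_path = Path(genotype_path)
    if format == "ped_map":
        ds = _read_ped_map(genotype_path)
    elif format == "dosage_table":
        ds = _read_dosage(genotype_path, phenotype_path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if format == "ped_map":
        ds = GenotypeDataset(
            subjects=_merge_phenotypes(ds.subjects, phenotype_path),
            snps=ds.snps,
            calls=ds.calls,
        )
    return ds


def _read_map(map_path: Path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise GenotypeFormatError(
                    f"{map_path}:{ln}: expected 4 columns (chrom snp_id cM bp), "
                    f"got {len(parts)}"
                )
            chrom, snp_id, _cm, bp = parts
            try:
                pos = int(bp)
            except ValueError as exc:
                raise GenotypeFormatError(
                    f"{map_path}:{ln}: position {bp!r} is not an integer"
                ) from exc
            rows.append({"snp_id": snp_id, "chrom": chrom, "pos_bp": pos})
    return pd.DataFrame(rows)


def _read_ped_map(ped_path: Path) -> GenotypeDataset:
    map_path = ped_path.with_suffix(".map")
    snp_map = _read_map(map_path)
    n_snps = len(snp_map)

    subject_ids: list[str] = []
    statuses: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise GenotypeFormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_snps} fields "
                    f"(6 leading + 2 per SNP), got {len(parts)}"
                )
            _fid, iid, _pat, _mat, _sex, pheno = parts[:6]
            if pheno not in ("1", "2"):
                raise GenotypeFormatError(
                    f"{ped_path}:{ln}: PHENO must be 1 (control) or 2 (case), got {pheno!r}"
                )
            subject_ids.append(iid)
            statuses.append("case" if pheno == "2" else "control")
            allele_rows.append(parts[6:])

    n_subj = len(subject_ids)
    calls = np.full((n_subj, n_snps), np.nan)
    snp_records = []
    for s in range(n_snps):
        a1 = [row[2 * s] for row in allele_rows]
        a2 = [row[2 * s + 1] for row in allele_rows]
        counts: dict[str, int] = {}
        for a in itertools.chain(a1, a2):
            if a != "0":
                counts[a] = counts.get(a, 0) + 1
        alleles = sorted(counts)
        if len(alleles) > 2:
            raise GenotypeFormatError(
                f"{ped_path}: SNP {snp_map['snp_id'][s]} has >2 alleles: {alleles}"
            )
        if not alleles:  # fully missing column
            alleles = ["A", "B"]
            counts = {"A": 0, "B": 0}
        if len(alleles) == 1:
            alleles.append(alleles[0] + "_alt")
            counts[alleles[1]] = 0
        # minor = less frequent; ties broken lexicographically (smaller string)
        minor, major = sorted(alleles, key=lambda a: (counts[a], a))
        n_obs = 0
        for j in range(n_subj):
            x, y = a1[j], a2[j]
            if x == "0" or y == "0":
                continue
            for tok in (x, y):
                if tok not in (major, minor):
                    raise GenotypeFormatError(
                        f"{ped_path}: subject {subject_ids[j]} SNP "
                        f"{snp_map['snp_id'][s]}: genotype token {tok!r} not in "
                        f"declared alleles {{{major}, {minor}}}"
                    )
            calls[j, s] = (x == minor) + (y == minor)
            n_obs += 1
        maf = float(np.nansum(calls[:, s]) / (2 * n_obs)) if n_obs else np.nan
        snp_records.append(
            {
                "snp_id": snp_map["snp_id"][s],
                "chrom": snp_map["chrom"][s],
                "pos_bp": snp_map["pos_bp"][s],
                "allele_major": major,
                "allele_minor": minor,
                "maf": maf,
            }
        )
    return GenotypeDataset(
        subjects=_default_subjects(subject_ids, statuses),
        snps=pd.DataFrame(snp_records, columns=SNP_COLUMNS),
        calls=calls,
    )


def _read_dosage(path: Path, phenotype_path: Path | None) -> GenotypeDataset:
    tbl = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in tbl.columns:
        raise GenotypeFormatError(f"{path}: dosage table needs a 'subject_id' column")
    snp_ids = [c for c in tbl.columns if c != "subject_id"]
    calls = tbl[snp_ids].to_numpy(dtype=float)
    bad = ~(np.isnan(calls) | np.isin(calls, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeFormatError(
            f"{path}: row {i + 2} (subject {tbl['subject_id'].iloc[i]}), column "
            f"{snp_ids[j]}: dosage entries must be 0/1/2/NA"
        )
    if phenotype_path is None:
        raise GenotypeFormatError(
            "dosage_table format requires a phenotype table for case/control status"
        )
    subjects = _merge_phenotypes(
        _default_subjects(tbl["subject_id"], ["control"] * len(tbl)), phenotype_path
    )
    # generic allele labels; flip so the stored allele is the sample-minor one
    snp_records = []
    for s, snp_id in enumerate(snp_ids):
        col = calls[:, s]
        obs = ~np.isnan(col)
        freq = col[obs].sum() / (2 * obs.sum()) if obs.any() else np.nan
        major, minor = "A", "B"
        if np.isfinite(freq) and freq > 0.5:
            calls[:, s] = 2 - col
            major, minor = "B", "A"
            freq = 1 - freq
        snp_records.append(
            {
                "snp_id": snp_id,
                "chrom": "1",
                "pos_bp": s + 1,
                "allele_major": major,
                "allele_minor": minor,
                "maf": float(freq),
            }
        )
    return GenotypeDataset(
        subjects=subjects,
        snps=pd.DataFrame(snp_records, columns=SNP_COLUMNS),
        calls=calls,
    )


def write_genotypes(ds: GenotypeDataset, prefix: Path, format: str = "ped_map") -> None:
    """Write a dataset as ``prefix.ped``/``prefix.map`` or ``prefix.dosage.tsv``
    plus ``prefix.pheno.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ds.subjects.to_csv(prefix.with_suffix(".pheno.tsv"), sep="\t", index=False)
    if format == "ped_map":
        with open(prefix.with_suffix(".map"), "w") as fh:
            for _, row in ds.snps.iterrows():
                fh.write(f"{row['chrom']}\t{row['snp_id']}\t0\t{row['pos_bp']}\n")
        with open(prefix.with_suffix(".ped"), "w") as fh:
            for i, subj in ds.subjects.iterrows():
                pheno = "2" if subj["status"] == "case" else "1"
                fields = [subj["subject_id"], subj["subject_id"], "0", "0", "0", pheno]
                for s in range(ds.n_snps):
                    call = ds.calls[i, s]
                    major = ds.snps["allele_major"].iloc[s]
                    minor = ds.snps["allele_minor"].iloc[s]
                    if np.isnan(call):
                        fields += ["0", "0"]
                    else:
                        n_minor = int(call)
                        fields += [minor] * n_minor + [major] * (2 - n_minor)
                fh.write("\t".join(fields) + "\n")
    elif format == "dosage_table":
        tbl = pd.DataFrame(ds.calls, columns=ds.snp_ids)
        tbl.insert(0, "subject_id", ds.subject_ids)
        out = prefix.parent / (prefix.name + ".dosage.tsv")
        tbl.to_csv(out, sep="\t", index=False, na_rep="NA", float_format="%.0f")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# panel operations
# ---------------------------------------------------------------------------


def filter_by_maf(ds: GenotypeDataset, threshold: float = 0.25) -> GenotypeDataset:
    """Retain exactly the SNPs with maf strictly greater than ``threshold``."""
    if not 0 <= threshold <= 0.5:
        raise ValueError("threshold must lie in [0, 0.5]")
    maf = ds.computed_maf()
    keep = np.flatnonzero(maf > threshold)
    return ds.subset_snps(keep)


def expand_allele_combinations(ds: GenotypeDataset) -> ComboMatrix:
    """Expand 0/1/2 calls into the 3-per-SNP signed combination encoding."""
    if ds.n_subjects == 0 or ds.n_snps == 0:
        raise ValueError("dataset must be non-empty")
    n, s = ds.calls.shape
    values = np.full((n, 3 * s), -1.0)
    for k, kind in enumerate(COMBO_KINDS):  # kind k corresponds to call == k
        values[:, k::3][ds.calls == k] = 1.0
    missing = np.isnan(ds.calls)
    for k in range(3):
        values[:, k::3][missing] = np.nan
    combos = pd.DataFrame(
        {
            "snp_id": np.repeat(ds.snp_ids, 3),
            "kind": np.tile(COMBO_KINDS, s),
        }
    )
    return ComboMatrix(ds.subject_ids.copy(), combos, values)


def combos_to_calls(cm: ComboMatrix) -> np.ndarray:
    """Invert the combination expansion back to 0/1/2 calls (NaN if missing)."""
    n = len(cm.subject_ids)
    s = len(cm.combos) // 3
    calls = np.full((n, s), np.nan)
    for k in range(3):
        hit = cm.values[:, k::3] == 1.0
        calls[hit] = k
    return calls


def snp_overlap_coefficient(panel_a: Iterable[str], panel_b: Iterable[str]) -> float:
    """Szymkiewicz-Simpson overlap |A∩B| / min(|A|, |B|)."""
    a, b = set(panel_a), set(panel_b)
    if not a or not b:
        raise ValueError("panels must be non-empty")
    return len(a & b) / min(len(a), len(b))


def restrict_to_panel(cm: ComboMatrix, snp_panel: Iterable[str]) -> ComboMatrix:
    """Keep only combos whose SNP is in ``snp_panel``, preserving order."""
    panel = set(snp_panel)
    keep = np.flatnonzero(cm.combos["snp_id"].isin(panel).to_numpy())
    return cm.restrict_combos(keep)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: Path, universe: set | None = None) -> PathwayCollection:
    """Read a GMT file (pathway_id <tab> description <tab> gene ...)."""
    pathways: dict[str, set] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise GenotypeFormatError(
                    f"{path}:{ln}: GMT lines need pathway, description and >=1 gene"
                )
            pathways[parts[0]] = set(g for g in parts[2:] if g)
    if universe is None:
        universe = set().union(*pathways.values()) if pathways else set()
    return PathwayCollection(pathways=pathways, universe=universe)


def read_gene_annotation(
    path: Path, panel_snp_ids: Iterable[str]
) -> GeneAnnotation:
    """Read a two-column gene->SNP table and expand SNPs to their 3 combos.

    SNPs absent from the analysis panel are flagged in ``unmatched_snps``
    rather than silently dropped without trace.
    """
    panel = set(panel_snp_ids)
    gene_to_combos: dict[str, set] = {}
    unmatched: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2:
                raise GenotypeFormatError(
                    f"{path}:{ln}: expected two columns (gene_id snp_id)"
                )
            gene, snp = parts
            if snp not in panel:
                unmatched.add(snp)
                continue
            gene_to_combos.setdefault(gene, set()).update(
                f"{snp}:{kind}" for kind in COMBO_KINDS
            )
    return GeneAnnotation(gene_to_combos=gene_to_combos, unmatched_snps=unmatched)


def annotation_from_mapping(
    gene_to_snps: Mapping[str, Iterable[str]], panel_snp_ids: Iterable[str]
) -> GeneAnnotation:
    """Build a GeneAnnotation from an in-memory gene -> SNP mapping."""
    panel = set(panel_snp_ids)
    gene_to_combos: dict[str, set] = {}
    unmatched: set[str] = set()
    for gene, snps in gene_to_snps.items():
        combos = set()
        for snp in snps:
            if snp in panel:
                combos.update(f"{snp}:{kind}" for kind in COMBO_KINDS)
            else:
                unmatched.add(snp)
        if combos:
            gene_to_combos[gene] = combos
    return GeneAnnotation(gene_to_combos=gene_to_combos, unmatched_snps=unmatched)
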