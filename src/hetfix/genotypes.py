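"""Genotype matrix container and marker-level I/O.

Genotypes are biallelic SNP-array calls stored as alternate-allele dosages
in {0, 1, 2}, with -1 encoding a missing call.  In an allo-octoploid crop
genotyped on an array these are *pseudo-diploid* calls: the array clusters
report three genotype classes per marker, not the true octoploid allele
dosage, and every statistic in this package operates on those calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

_MARKER_COLUMNS = ["marker_id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with marker metadata.

    Parameters
    ----------
    ids : list of str
        Individual identifiers (rows).
    markers : pandas.DataFrame
        One row per marker with columns ``marker_id, chrom, pos, ref, alt``.
    calls : ndarray of int8, shape (n_individuals, n_markers)
        Alternate-allele dosage in {0, 1, 2}; -1 marks a missing call.
    """

    ids: list[str]
    markers: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.ids), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.ids)} individuals x {len(self.markers)} markers"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual IDs")
        mid = self.markers["marker_id"]
        if mid.duplicated().any():
            raise ValueError("duplicate marker IDs")
        if (self.markers["pos"] < 0).any():
            raise ValueError("negative marker positions")
        bad = ~np.isin(self.calls, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("calls must be in {0,1,2} or -1 (missing)")
        self._index = {s: i for i, s in enumerate(self.ids)}

    # -- basic access -------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def row(self, individual: str) -> np.ndarray:
        return self.calls[self._index[individual]]

    def subset(self, individuals=None, marker_mask=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given individuals and/or markers."""
        calls = self.calls
        ids = self.ids
        markers = self.markers
        if individuals is not None:
            rows = [self._index[s] for s in individuals]
            calls = calls[rows]
            ids = list(individuals)
        if marker_mask is not None:
            marker_mask = np.asarray(marker_mask)
            calls = calls[:, marker_mask]
            markers = markers.loc[marker_mask].reset_index(drop=True)
        return GenotypeMatrix(ids, markers.copy(), calls.copy())

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def allele_frequencies(self) -> np.ndarray:
        """Per-marker alternate-allele frequency over nonmissing calls.

        Markers with no nonmissing calls get frequency nan.
        """
        c = np.where(self.calls == MISSING, np.nan, self.calls.astype(float))
        with np.errstate(invalid="ignore"):
            return np.nanmean(c, axis=0) / 2.0

    def dosage_float(self) -> np.ndarray:
        """Calls as float with missing -> nan."""
        return np.where(self.calls == MISSING, np.nan, self.calls.astype(float))

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Dosage matrix as CSV: rows = individuals, cols = marker IDs, NA = missing."""
        df = pd.DataFrame(
            self.dosage_float(), index=self.ids, columns=self.markers["marker_id"]
        )
        df.to_csv(path, index_label="individual", na_rep="NA")

    @classmethod
    def from_csv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, index_col=0)
        calls = df.to_numpy(dtype=float)
        calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
        markers = default_marker_table(list(df.columns))
        return cls([str(s) for s in df.index], markers, calls)

    def to_vcf(self, path) -> None:
        """Write a minimal biallelic VCF with GT genotypes (1-based positions)."""
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            chroms = pd.unique(self.markers["chrom"])
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.ids)
                + "\n"
            )
            for j, m in enumerate(self.markers.itertuples(index=False)):
                gts = "\t".join(gt_map[int(g)] for g in self.calls[:, j])
                fh.write(
                    f"{m.chrom}\t{int(m.pos)}\t{m.marker_id}\t{m.ref}\t{m.alt}"
                    f"\t.\tPASS\t.\tGT\t{gts}\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read a biallelic VCF; GT -> dosage, ./. -> missing."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        ids = list(vcf.samples)
        rows = []
        recs = []
        for v in vcf:
            # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = np.array(v.gt_types)
            dos = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
            rows.append(dos.astype(np.int8))
            recs.append(
                (v.ID or f"{v.CHROM}_{v.POS}", v.CHROM, v.POS, v.REF, v.ALT[0])
            )
        vcf.close()
        markers = pd.DataFrame(recs, columns=_MARKER_COLUMNS)
        return cls(ids, markers, np.array(rows, dtype=np.int8).T)


def default_marker_table(
    marker_ids: list[str], n_chromosomes: int = 1, chrom_prefix: str = "chr"
) -> pd.DataFrame:
    """Evenly spread markers across chromosomes with 1-based positions."""
    m = len(marker_ids)
    per = int(np.ceil(m / n_chromosomes))
    chroms = [f"{chrom_prefix}{i // per + 1}" for i in range(m)]
    pos = [(i % per) * 1000 + 1 for i in range(m)]
    return pd.DataFrame(
        {
            "marker_id": marker_ids,
            "chrom": chroms,
            "pos": pos,
            "ref": "A",
            "alt": "B",
        }
    )
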