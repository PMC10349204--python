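"""Diploid microsatellite genotype tables.

A :class:`GenotypeTable` stores individuals x loci diploid allele sizes
(integer repeat counts) with site and population labels.  Missing calls are
explicit (-1 sentinel in the allele array, never zero-coded internally).
Round-trips through GenePop (2- or 3-digit allele coding, autodetected on
read) and a tidy CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeTable:
    individuals: pd.DataFrame  # columns: id, site, population
    loci: list
    alleles: np.ndarray  # (n_individuals, n_loci, 2) int; MISSING = -1

    def __post_init__(self):
        self.individuals = self.individuals.reset_index(drop=True)
        for col in ("id", "site", "population"):
            if col not in self.individuals.columns:
                raise ValueError(f"individuals table needs column '{col}'")
        self.loci = [str(x) for x in self.loci]
        self.alleles = np.asarray(self.alleles, dtype=np.int32)
        if self.alleles.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError("alleles array shape must be (n_individuals, n_loci, 2)")
        bad = (self.alleles != MISSING) & (self.alleles < 1)
        if bad.any():
            raise ValueError("allele sizes must be positive integers (missing = -1)")
        if self.individuals["id"].duplicated().any():
            raise ValueError("individual ids must be unique")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list:
        return sorted(self.individuals["population"].unique())

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean: call missing (either allele missing)."""
        return (self.alleles == MISSING).any(axis=2)

    def missing_alleles_per_individual(self) -> np.ndarray:
        """Number of missing alleles (not loci) per individual."""
        return (self.alleles == MISSING).sum(axis=(1, 2))

    def subset(self, index) -> "GenotypeTable":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.nonzero(index)[0]
        return GenotypeTable(self.individuals.iloc[index], list(self.loci), self.alleles[index])

    def population_indices(self) -> dict:
        return {p: np.nonzero((self.individuals["population"] == p).values)[0]
                for p in self.populations}

    def relabel_populations(self, site_to_pop: dict) -> "GenotypeTable":
        """Replace population labels using a site -> population mapping."""
        pops = self.individuals["site"].map(site_to_pop)
        if pops.isna().any():
            missing = sorted(self.individuals.loc[pops.isna(), "site"].unique())
            raise ValueError(f"sites without a population assignment: {missing}")
        ind = self.individuals.copy()
        ind["population"] = pops.values
        return GenotypeTable(ind, list(self.loci), self.alleles)

    # -- tidy CSV ----------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        n, L = self.n_individuals, self.n_loci
        rows = {
            "individual": np.repeat(self.individuals["id"].values, L),
            "site": np.repeat(self.individuals["site"].values, L),
            "population": np.repeat(self.individuals["population"].values, L),
            "locus": np.tile(np.asarray(self.loci, dtype=object), n),
            "allele1": self.alleles[:, :, 0].ravel().astype(object),
            "allele2": self.alleles[:, :, 1].ravel().astype(object),
        }
        df = pd.DataFrame(rows)
        df.loc[df["allele1"] == MISSING, "allele1"] = ""
        df.loc[df["allele2"] == MISSING, "allele2"] = ""
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GenotypeTable":
        df = pd.read_csv(path, dtype={"individual": str, "site": str, "population": str})
        loci = list(dict.fromkeys(df["locus"].astype(str)))
        ind = (df[["individual", "site", "population"]]
               .drop_duplicates("individual").reset_index(drop=True)
               .rename(columns={"individual": "id"}))
        n, L = len(ind), len(loci)
        alleles = np.full((n, L, 2), MISSING, dtype=np.int32)
        ind_pos = {v: i for i, v in enumerate(ind["id"])}
        loc_pos = {v: j for j, v in enumerate(loci)}
        ii = df["individual"].map(ind_pos).values
        jj = df["locus"].astype(str).map(loc_pos).values
        for k, col in enumerate(("allele1", "allele2")):
            vals = pd.to_numeric(df[col], errors="coerce").fillna(MISSING).astype(int).values
            alleles[ii, jj, k] = vals
        return cls(ind, loci, alleles)

    # -- GenePop -----------------------------------------------------------
    def to_genepop(self, path: str | Path, title: str = "seaflow genotypes") -> None:
        """Write GenePop with 2-digit allele coding (3-digit if any size > 99).

        Individual names encode ``population|site|id`` so labels survive the
        round trip; missing alleles are written as zeros, per the format.
        """
        digits = 3 if (self.alleles > 99).any() else 2
        fmt = f"0{digits}d"
        lines = [title]
        lines.extend(self.loci)
        for pop in self.populations:
            lines.append("Pop")
            for i in np.nonzero((self.individuals["population"] == pop).values)[0]:
                row = self.individuals.iloc[i]
                geno = []
                for j in range(self.n_loci):
                    a, b = self.alleles[i, j]
                    a = 0 if a == MISSING else a
                    b = 0 if b == MISSING else b
                    geno.append(format(a, fmt) + format(b, fmt))
                lines.append(f"{row['population']}|{row['site']}|{row['id']} ,  " + " ".join(geno))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_genepop(cls, path: str | Path) -> "GenotypeTable":
        text = Path(path).read_text().strip().splitlines()
        header, body = text[0], text[1:]
        loci: list[str] = []
        k = 0
        while k < len(body) and body[k].strip().lower() != "pop":
            # locus names may be one per line or comma-separated
            loci.extend(s.strip() for s in body[k].split(",") if s.strip())
            k += 1
        recs = []
        pop_idx = 0
        for line in body[k:]:
            if line.strip().lower() == "pop":
                pop_idx += 1
                continue
            if not line.strip():
                continue
            name, geno_str = line.split(",", 1)
            name = name.strip()
            genos = geno_str.split()
            if len(genos) != len(loci):
                raise ValueError(f"individual '{name}' has {len(genos)} genotypes for {len(loci)} loci")
            parts = name.split("|")
            if len(parts) == 3:
                pop, site, ind_id = parts
            else:
                pop, site, ind_id = f"pop{pop_idx}", f"pop{pop_idx}", name
            recs.append((ind_id, site, pop, genos))
        if not recs:
            raise ValueError("GenePop file contains no individuals")
        digits = len(recs[0][3][0]) // 2
        n, L = len(recs), len(loci)
        alleles = np.full((n, L, 2), MISSING, dtype=np.int32)
        for i, (_, _, _, genos) in enumerate(recs):
            for j, g in enumerate(genos):
                a, b = int(g[:digits]), int(g[digits:])
                alleles[i, j, 0] = a if a > 0 else MISSING
                alleles[i, j, 1] = b if b > 0 else MISSING
        ind = pd.DataFrame({"id": [r[0] for r in recs], "site": [r[1] for r in recs],
                            "population": [r[2] for r in recs]})
        return cls(ind, loci, alleles)
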