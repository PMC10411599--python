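"""Cross-species sharing of TSS-bearing gene symbols.

Given one set of gene symbols with at least one annotated TSS per
species, plus the designation of an avian outgroup and a focal (human)
set, each symbol in the union is classified into one of:

* ``avian/mammalian`` — present in every species;
* ``mammalian-specific`` — present in every mammal but not the outgroup;
* ``human-specific`` — present only in the focal human set;
* ``species-specific:<name>`` — present in exactly one non-human species;
* ``partial-shared`` — any other sharing pattern (explicit residual
  class; the four named groups alone do not cover all patterns).

Matching is exact on uppercase-normalized symbols; paralogs and symbol
synonyms are deliberately not resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class SymbolCatalog:
    """Per-species sets of TSS-bearing gene symbols with role designations."""

    species: dict[str, set[str]]
    outgroup: str
    focal: str

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("empty catalog")
        if len(self.species) < 3:
            raise ValueError("need at least 3 species")
        if self.outgroup not in self.species:
            raise ValueError(f"outgroup {self.outgroup!r} not in catalog")
        if self.focal not in self.species:
            raise ValueError(f"focal species {self.focal!r} not in catalog")
        self.species = {name: {s.upper() for s in symbols} for name, symbols in self.species.items()}

    @property
    def mammals(self) -> list[str]:
        return [name for name in self.species if name != self.outgroup]


def classify_symbol_groups(catalog: SymbolCatalog) -> pd.DataFrame:
    """One row per symbol in the union, with its sharing group label."""
    universe = sorted(set().union(*catalog.species.values()))
    all_species = set(catalog.species)
    mammals = set(catalog.mammals)
    rows = []
    for symbol in universe:
        present = {name for name, symbols in catalog.species.items() if symbol in symbols}
        if present == all_species:
            group = "avian/mammalian"
        elif present == mammals:
            group = "mammalian-specific"
        elif present == {catalog.focal}:
            group = "human-specific"
        elif len(present) == 1:
            group = f"species-specific:{next(iter(present))}"
        else:
            group = "partial-shared"
        rows.append((symbol, group, len(present)))
    return pd.DataFrame(rows, columns=["symbol", "group", "n_species"])


def species_summary(clusters_per_species: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-species TSS count, annotated-gene count and TSS-per-gene ratio.

    Cluster frames must carry ``gene_id`` and ``is_novel``.  The ratio is
    rounded to 1 decimal and left blank for species without annotated
    genes.  Rows are sorted by descending TSS count, ties broken by
    species name.
    """
    rows = []
    for name in sorted(clusters_per_species):
        df = clusters_per_species[name]
        n_tss = len(df)
        n_genes = df.loc[~df["is_novel"], "gene_id"].nunique()
        ratio = round(n_tss / n_genes, 1) if n_genes else float("nan")
        rows.append((name, n_tss, n_genes, ratio))
    out = pd.DataFrame(rows, columns=["species", "n_tss", "n_genes", "tss_per_gene"])
    return out.sort_values(["n_tss", "species"], ascending=[False, True], kind="mergesort").reset_index(
        drop=True
    )


def read_symbol_lists(paths: dict[str, str], outgroup: str, focal: str) -> SymbolCatalog:
    """Build a catalog from one plain-text symbol list per species."""
    species = {}
    for name, path in paths.items():
        with open(path) as fh:
            species[name] = {line.strip() for line in fh if line.strip()}
    return SymbolCatalog(species=species, outgroup=outgroup, focal=focal)
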