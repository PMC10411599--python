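"""Cross-species sharing groups for TSS-bearing gene symbols.

Given per-species sets of gene symbols with annotated TSS, an avian
outgroup and a focal human set, each symbol is classified as
avian/mammalian, mammalian-specific, human-specific,
species-specific:<name>, or partial-shared (the explicit residual).
"""

from cagecall.crossspecies import SymbolCatalog, classify_symbol_groups, species_summary

species = {
    "human":   {"TP53", "MYC", "ACTB", "GAPDH", "FOXP2", "HSONLY1", "HSONLY2"},
    "mouse":   {"TP53", "MYC", "ACTB", "GAPDH", "FOXP2"},
    "rat":     {"TP53", "MYC", "ACTB", "GAPDH", "FOXP2"},
    "dog":     {"TP53", "MYC", "ACTB", "GAPDH"},
    "macaque": {"TP53", "MYC", "ACTB", "GAPDH", "FOXP2"},
    "cattle":  {"TP53", "MYC", "ACTB", "GAPDH", "FOXP2", "BOVONLY"},
    "sheep":   {"TP53", "MYC", "ACTB", "GAPDH", "FOXP2"},
    "chicken": {"TP53", "ACTB", "GAPDH"},
}
catalog = SymbolCatalog(species=species, outgroup="chicken", focal="human")
groups = classify_symbol_groups(catalog)
print(groups.to_string(index=False))
print("\ncounts per group:")
print(groups["group"].value_counts().to_string())
# TP53/ACTB/GAPDH are avian/mammalian (all 8 sets); MYC and FOXP2 differ:
# MYC is in all mammals but not chicken -> mammalian-specific, while FOXP2
# is missing from dog too -> partial-shared, the residual pattern the four
# named groups do not cover.
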