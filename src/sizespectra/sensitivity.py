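"""Sensitivity variants of the base analysis.

Five configurations are supported, differing in truncation offsets,
catalog source, and realm coverage:

=========  ==========================  =================  ==================
label      truncation (below/above)    catalog            notes
=========  ==========================  =================  ==================
A_base     -2 / +0 decades             base               the main analysis
B_wide     -1 / +1                     base
C_tight    -0 / +0                     base
D_ramet    -2 / +0                     ramet sizes        user-supplied CSV
E_active   -2 / +0                     active-mass only   user-supplied CSV;
                                                          subterranean
                                                          microbes excluded
=========  ==========================  =================  ==================

The ramet and metabolically-active catalogs are not packaged (their
values live in supplementary tables outside the transcribed base
tables); variants D and E therefore require a catalog path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .catalog import Catalog, load_base_catalog, load_catalog
from .gev import FitConfig
from .pipeline import DEFAULT_REALM_SETS, PipelineResult, RunConfig, run_pipeline

__all__ = ["VariantConfig", "VARIANTS", "variant_run_config", "run_variant"]


@dataclass(frozen=True)
class VariantConfig:
    label: str
    lower_offset: float
    upper_offset: float
    catalog_source: str  # "base" | "ramet" | "active_only"
    exclude_realms: tuple[str, ...] = ()


VARIANTS: dict[str, VariantConfig] = {
    "A_base": VariantConfig("A_base", 2.0, 0.0, "base"),
    "B_wide": VariantConfig("B_wide", 1.0, 1.0, "base"),
    "C_tight": VariantConfig("C_tight", 0.0, 0.0, "base"),
    "D_ramet": VariantConfig("D_ramet", 2.0, 0.0, "ramet"),
    "E_active": VariantConfig(
        "E_active", 2.0, 0.0, "active_only", exclude_realms=("subterranean",)
    ),
}


class VariantCatalogRequired(FileNotFoundError):
    """Variant needs a user-supplied catalog that was not given."""


def variant_run_config(
    variant: VariantConfig | str,
    n_boot: int = 1000,
    seed: int = 0,
    catalog_path: str | None = None,
    **overrides,
) -> RunConfig:
    """Translate a variant row into a pipeline RunConfig."""
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    if variant.catalog_source != "base" and catalog_path is None:
        raise VariantCatalogRequired(
            f"variant {variant.label} requires a user-supplied "
            f"{variant.catalog_source} catalog CSV"
        )
    realm_sets = {
        label: tuple(r for r in realms if r not in variant.exclude_realms)
        for label, realms in DEFAULT_REALM_SETS.items()
    }
    realm_sets = {k: v for k, v in realm_sets.items() if v}
    base = RunConfig(
        catalog_path=catalog_path,
        variant_label=variant.label,
        n_boot=n_boot,
        seed=seed,
        fit=FitConfig(
            lower_offset=variant.lower_offset,
            upper_offset=variant.upper_offset,
        ),
        realm_sets=realm_sets,
    )
    return dataclasses.replace(base, **overrides) if overrides else base


def run_variant(
    variant: VariantConfig | str,
    n_boot: int = 1000,
    seed: int = 0,
    catalog_path: str | None = None,
    **overrides,
) -> PipelineResult:
    """Run the full pipeline under one sensitivity configuration."""
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    config = variant_run_config(
        variant, n_boot=n_boot, seed=seed, catalog_path=catalog_path, **overrides
    )
    if variant.catalog_source == "base" and catalog_path is None:
        catalog = load_base_catalog()
    else:
        catalog = load_catalog(catalog_path, variant_label=variant.label)
    if variant.exclude_realms:
        catalog = Catalog(
            records=tuple(
                g for g in catalog if g.realm not in variant.exclude_realms
            ),
            variant_label=catalog.variant_label,
        )
    return run_pipeline(config, catalog=catalog)
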