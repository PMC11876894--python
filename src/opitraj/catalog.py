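"""Synthetic drug catalog.

Claims rows carry only a ``drug_id`` plus strength/quantity/days-supply; the
morphine-milligram-equivalent (MME) conversion factor for each opioid lives in
a catalog (mirroring how published CDC conversion tables are versioned outside
any analysis code).  The catalog bundled here is synthetic: drug identifiers
are generic and strengths/factors are typical oral formulations, sufficient to
drive the simulator and the dose arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

DRUG_CLASSES = ("opioid", "stimulant", "buprenorphine", "other")
ROUTES = ("oral", "patch", "injection", "other")


@dataclass(frozen=True)
class Drug:
    """One dispensable product: class, route, per-unit strength and MME factor."""

    drug_id: str
    drug_class: str  # one of DRUG_CLASSES
    route: str  # one of ROUTES
    strength_mg: float  # strength per unit (mg)
    mme_factor: float | None = None  # dimensionless; opioids only

    def validate(self) -> None:
        from .errors import ConfigurationError

        if self.drug_class not in DRUG_CLASSES:
            raise ConfigurationError(f"drug_catalog[{self.drug_id}].drug_class: {self.drug_class!r}")
        if self.route not in ROUTES:
            raise ConfigurationError(f"drug_catalog[{self.drug_id}].route: {self.route!r}")
        if not self.strength_mg > 0:
            raise ConfigurationError(f"drug_catalog[{self.drug_id}].strength_mg must be > 0")
        if self.drug_class == "opioid":
            if self.mme_factor is None or not self.mme_factor > 0:
                raise ConfigurationError(
                    f"drug_catalog[{self.drug_id}].mme_factor must be > 0 for opioids"
                )

    def to_dict(self) -> dict:
        return asdict(self)


def default_drug_catalog() -> tuple[Drug, ...]:
    """A small synthetic catalog covering every class/route the pipeline exercises."""
    return (
        Drug("OPI-A", "opioid", "oral", 5.0, 1.5),    # oxycodone-like
        Drug("OPI-B", "opioid", "oral", 10.0, 1.0),   # hydrocodone-like
        Drug("OPI-C", "opioid", "oral", 15.0, 1.0),   # morphine-like
        Drug("OPI-P", "opioid", "patch", 12.0, 2.4),  # transdermal; excluded by route rules
        Drug("STM-A", "stimulant", "oral", 10.0, None),
        Drug("STM-B", "stimulant", "oral", 20.0, None),
        Drug("BUP-A", "buprenorphine", "oral", 2.0, None),
        Drug("OTH-A", "other", "oral", 200.0, None),
    )


def catalog_from_dicts(rows) -> tuple[Drug, ...]:
    drugs = tuple(Drug(**row) for row in rows)
    for d in drugs:
        d.validate()
    return drugs


def mme_factor_map(catalog) -> dict[str, float]:
    """drug_id → MME conversion factor for the opioids in ``catalog``."""
    return {d.drug_id: d.mme_factor for d in catalog if d.drug_class == "opioid"}
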