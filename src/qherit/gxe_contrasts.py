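"""Genotype-by-condition interaction algebra on published means tables.

A 2 (condition) x G (genotype) table of mean phenotype levels supports two
equivalent readings of the same interaction: condition differences within
genotype, dC(g) = mean(g, c1) - mean(g, c2), and genotype differences within
condition, dG(c) = mean(g1, c) - mean(g2, c).  They are tied by the identity

    dC(g1) - dC(g2) = dG(c1) - dG(c2)

which lets a published interaction expressed one way be pivoted into the
other (``pivot_interaction``), checked for transcription errors
(``consistency_check``), and re-plotted as genotype effect size versus the
condition's mean phenotype level (``build_line_graph``) — the display that
shows whether the genetic effect is larger where the phenotype is higher.

Standard errors are echoed only when the source printed them; the SE of a
pivoted difference is never synthesised from the other three (their
covariance in the source study is unknown).

A corpus of tables transcribed from published leptin gene-environment
studies ships with the package; ``load_study``/``list_studies`` access it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

logger = logging.getLogger("qherit")

#: |residual| above this (ng/ml) triggers a transcription warning; published
#: values are rounded to 1 decimal place, so small residuals are expected
ROUNDING_TOL = 0.15


@dataclass
class GxEMeansTable:
    """A genotype x condition table of published phenotype means.

    ``genotypes`` is ordered; genotype differences are genotypes[0] minus
    genotypes[1].  ``conditions`` has exactly two entries; condition
    differences are conditions[0] minus conditions[1].  A table may carry
    full cell means, or only the published differences ("differences form").
    ``status`` is ``"full"`` when both sides of the interaction identity can
    be evaluated, else ``"partial"``.
    """

    study: str
    genotypes: list[str]
    conditions: list[str]
    source: str = ""
    units: str = "ng/ml"
    status: str = "full"
    cell_means: dict = field(default_factory=dict)      # {genotype: {condition: value}}
    cell_ses: dict = field(default_factory=dict)
    condition_differences: dict = field(default_factory=dict)   # {genotype: value}
    condition_difference_ses: dict = field(default_factory=dict)
    genotype_differences: dict = field(default_factory=dict)    # {condition: value}
    genotype_difference_ses: dict = field(default_factory=dict)
    condition_means: dict = field(default_factory=dict)         # {condition: value}
    condition_mean_ses: dict = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are required")
        if len(self.genotypes) < 2:
            raise ValueError("at least two genotype labels are required")
        for ses in (self.cell_ses, self.condition_difference_ses,
                    self.genotype_difference_ses, self.condition_mean_ses):
            flat = []
            for v in ses.values():
                flat.extend(v.values() if isinstance(v, dict) else [v])
            if any(s < 0 for s in flat):
                raise ValueError("standard errors must be non-negative")

    # -- derived differences -------------------------------------------------

    def dC(self, genotype: str) -> float:
        """Condition difference (conditions[0] - conditions[1]) within genotype."""
        if genotype in self.condition_differences:
            return float(self.condition_differences[genotype])
        cells = self.cell_means.get(genotype, {})
        c1, c2 = self.conditions
        if c1 in cells and c2 in cells:
            return float(cells[c1]) - float(cells[c2])
        raise KeyError(f"{self.study}: condition difference for genotype {genotype!r} "
                       "is neither given nor derivable from cell means")

    def dG(self, condition: str) -> float:
        """Genotype difference (genotypes[0] - genotypes[1]) within condition."""
        if condition in self.genotype_differences:
            return float(self.genotype_differences[condition])
        g1, g2 = self.genotypes[:2]
        try:
            return (float(self.cell_means[g1][condition])
                    - float(self.cell_means[g2][condition]))
        except KeyError:
            raise KeyError(f"{self.study}: genotype difference in condition "
                           f"{condition!r} is neither given nor derivable") from None

    def mean_level(self, condition: str) -> float:
        """Mean phenotype level of a condition (published pooled mean if any,
        else the unweighted mean of the genotype cell means)."""
        if condition in self.condition_means:
            return float(self.condition_means[condition])
        missing = [g for g in self.genotypes
                   if condition not in self.cell_means.get(g, {})]
        if missing:
            raise KeyError(f"{self.study}: no pooled mean for {condition!r} and "
                           f"missing cell means for genotypes {missing}")
        return float(sum(self.cell_means[g][condition] for g in self.genotypes)
                     / len(self.genotypes))


@dataclass
class GxEContrasts:
    """The interaction re-expressed both ways, with the identity residual."""

    study: str
    condition_differences: dict          # dC(g), conditions[0]-conditions[1]
    genotype_differences: dict           # dG(c), genotypes[0]-genotypes[1]
    interaction: float                   # dC(g1)-dC(g2) == dG(c1)-dG(c2)
    condition_levels: dict               # mean phenotype level per condition
    identity_residual: float


def pivot_interaction(dc_g1: float, dc_g2: float, dg_c2: float) -> float:
    """Recover dG(c1) from dC(g1), dC(g2) and dG(c2) via the interaction identity.

    Sign conventions must be aligned: both dC values are condition1 minus
    condition2 within genotype, and both dG values are genotype1 minus
    genotype2 within condition, with the same genotype1/condition1 throughout.
    """
    return dg_c2 + (dc_g1 - dc_g2)


def consistency_residual(dc_g1: float, dc_g2: float, dg_c1: float, dg_c2: float
                         ) -> float:
    """Identity residual [dC(g1) - dC(g2)] - [dG(c1) - dG(c2)]."""
    return (dc_g1 - dc_g2) - (dg_c1 - dg_c2)


def consistency_check(table: GxEMeansTable, tol: float = ROUNDING_TOL) -> float:
    """Evaluate the interaction identity residual for a table.

    Exactly zero when all four differences come from one unrounded means
    table; published values rounded to 1 d.p. may leave a residual up to
    ``tol``, above which a transcription warning is logged.  Raises if the
    table does not determine both sides of the identity.
    """
    g1, g2 = table.genotypes[:2]
    c1, c2 = table.conditions
    try:
        res = consistency_residual(table.dC(g1), table.dC(g2),
                                   table.dG(c1), table.dG(c2))
    except KeyError as e:
        raise ValueError(f"under-determined table: {e}") from None
    if abs(res) > tol:
        logger.warning("%s: interaction identity residual %.3g exceeds the "
                       "rounding tolerance %.3g — check the transcription",
                       table.study, res, tol)
    return float(res)


def contrasts(table: GxEMeansTable) -> GxEContrasts:
    """Compute both difference readings and the identity residual."""
    g1, g2 = table.genotypes[:2]
    c1, c2 = table.conditions
    dC = {g: table.dC(g) for g in (g1, g2)}
    dG = {c: table.dG(c) for c in (c1, c2)}
    return GxEContrasts(
        study=table.study,
        condition_differences=dC,
        genotype_differences=dG,
        interaction=dC[g1] - dC[g2],
        condition_levels={c: table.mean_level(c) for c in table.conditions},
        identity_residual=consistency_residual(dC[g1], dC[g2], dG[c1], dG[c2]),
    )


def build_line_graph(table: GxEMeansTable) -> list[dict]:
    """Series of (condition mean level, genotype effect size), ordered by level.

    One point per condition: x is the condition's mean phenotype level, y is
    the genotype difference dG within that condition.  A rising series is the
    signature of quantile-dependent expressivity: the genetic effect is
    larger where the average phenotype is higher.
    """
    points = []
    for c in table.conditions:
        points.append({
            "condition": c,
            "level": table.mean_level(c),
            "genotype_effect": table.dG(c),
            "se": table.genotype_difference_ses.get(c),
        })
    points.sort(key=lambda d: d["level"])
    return points


# -- fixture corpus ----------------------------------------------------------

def _unpack(block: dict | None) -> tuple[dict, dict]:
    """Split {label: value | {value, se}} into value and SE dicts."""
    vals: dict = {}
    ses: dict = {}
    for k, v in (block or {}).items():
        if isinstance(v, dict):
            vals[k] = float(v["value"])
            if v.get("se") is not None:
                ses[k] = float(v["se"])
        else:
            vals[k] = float(v)
    return vals, ses


def table_from_dict(d: dict) -> GxEMeansTable:
    dC, dC_se = _unpack(d.get("condition_differences"))
    dG, dG_se = _unpack(d.get("genotype_differences"))
    cm, cm_se = _unpack(d.get("condition_means"))
    cells: dict = {}
    cell_ses: dict = {}
    for g, row in (d.get("cell_means") or {}).items():
        cells[g], ses = _unpack(row)
        if ses:
            cell_ses[g] = ses
    return GxEMeansTable(
        study=d["study"], genotypes=list(d["genotypes"]),
        conditions=list(d["conditions"]), source=d.get("source", ""),
        units=d.get("units", "ng/ml"), status=d.get("status", "full"),
        cell_means=cells, cell_ses=cell_ses,
        condition_differences=dC, condition_difference_ses=dC_se,
        genotype_differences=dG, genotype_difference_ses=dG_se,
        condition_means=cm, condition_mean_ses=cm_se,
        notes=d.get("notes", ""),
    )


def load_study(name: str | Path) -> GxEMeansTable:
    """Load a shipped study fixture by name, or any YAML table by path."""
    p = Path(name)
    if p.suffix in (".yaml", ".yml") and p.exists():
        text = p.read_text()
    else:
        ref = resources.files("qherit.data.gxe") / f"{name}.yaml"
        if not ref.is_file():
            raise FileNotFoundError(
                f"no shipped study {name!r}; available: {list_studies()}")
        text = ref.read_text()
    return table_from_dict(yaml.safe_load(text))


def list_studies() -> list[str]:
    return sorted(f.name[:-5] for f in resources.files("qherit.data.gxe").iterdir()
                  if f.name.endswith(".yaml"))
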