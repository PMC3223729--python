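"""End-to-end analysis runner and machine-readable provenance.

``run_full_analysis`` chains the stages — synthetic library generation,
per-mass candidate enumeration, the three-regime degeneracy comparison,
and (optionally) pathway-uniqueness analysis — and writes every table
as CSV plus a provenance record (configuration, seed, package versions)
so a run can be reproduced exactly.  Plots are deliberately not part of
the bundle: the CSV tables are the testable surface.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .chemspace import ElementRanges
from .constraints import compare_regimes
from .enumeration import HeuristicFilterConfig
from .pathways import drop_super_pathways, restrict_to_chnops, uniqueness_analysis
from .synthetic import LibrarySpec, PathwayDBSpec, generate_library, generate_pathway_db

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full analysis run."""

    out_dir: str = "silform_run"
    seed: int = 42
    library_size: int = 300
    mass_min: float = 50.0
    mass_max: float = 2000.0
    tolerance_ppm: float = 5.0
    rel_uncertainty: float = 0.10
    sample_size: int | None = None
    use_heuristic_filter: bool = False
    ranges: ElementRanges = field(default_factory=ElementRanges)
    pathway_spec: PathwayDBSpec | None = None
    log_level: str = "INFO"


def _provenance(config: RunConfig) -> dict:
    import numpy
    import pandas

    from . import __version__

    cfg = dataclasses.asdict(config)
    cfg["ranges"] = {e: list(b) for e, b in zip("CHNOSP", config.ranges.bounds())}
    if config.pathway_spec is not None:
        cfg["pathway_spec"] = dataclasses.asdict(config.pathway_spec)
        cfg["pathway_spec"]["ranges"] = None
    return {
        "config": cfg,
        "seed": config.seed,
        "versions": {
            "silform": __version__,
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
        },
    }


def run_full_analysis(config: RunConfig) -> dict[str, Path]:
    """Run the pipeline and write the report bundle.

    Returns a map of artifact name to file path.  Any stage failure is
    re-raised as a stage-named :class:`StageError`; artifacts written by
    earlier stages are preserved.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    prov_path = out / "provenance.json"
    prov_path.write_text(json.dumps(_provenance(config), indent=1, default=str))
    artifacts["provenance"] = prov_path

    try:
        spec = LibrarySpec(
            n_formulae=config.library_size,
            ranges=config.ranges,
            mass_min=config.mass_min,
            mass_max=config.mass_max,
            seed=config.seed,
        )
        library = generate_library(spec)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("generate_library", exc) from exc
    lib_path = out / "library.tsv"
    from .chemspace import write_compound_table

    write_compound_table(lib_path, library)
    artifacts["library"] = lib_path

    try:
        filter_config = (
            HeuristicFilterConfig() if config.use_heuristic_filter else None
        )
        report = compare_regimes(
            library,
            tolerance_ppm=config.tolerance_ppm,
            rel_uncertainty=config.rel_uncertainty,
            ranges=config.ranges,
            sample_size=config.sample_size,
            seed=config.seed,
            filter_config=filter_config,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("compare_regimes", exc) from exc

    n_rejected = int(report.per_mass["truth_rejected"].sum())
    if n_rejected:
        logger.warning(
            "heuristic filter rejected the true formula for %d/%d masses",
            n_rejected,
            len(report.per_mass),
        )

    degen_path = out / "degeneracy.csv"
    report.per_mass.to_csv(degen_path, index=False)
    artifacts["degeneracy"] = degen_path

    strat_path = out / "regime_stratification.csv"
    report.regime_stratification().to_csv(strat_path, index=False)
    artifacts["regime_stratification"] = strat_path

    bins_path = out / "winners_by_mass_bin.csv"
    report.winners_by_mass_bin().to_csv(bins_path, index=False)
    artifacts["winners_by_mass_bin"] = bins_path

    if config.pathway_spec is not None:
        try:
            db, ground_truth = generate_pathway_db(config.pathway_spec)
            clean = drop_super_pathways(restrict_to_chnops(db))
            uniq = uniqueness_analysis(clean)
        except Exception as exc:  # noqa: BLE001
            raise StageError("pathway_uniqueness", exc) from exc
        pwy_path = out / "pathway_uniqueness.csv"
        uniq.to_frame().to_csv(pwy_path, index=False)
        artifacts["pathway_uniqueness"] = pwy_path
        truth_path = out / "pathway_ground_truth.json"
        truth_path.write_text(json.dumps(ground_truth, indent=1))
        artifacts["pathway_ground_truth"] = truth_path

    return artifacts
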