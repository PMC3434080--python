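"""End-to-end driver: dedup, genotype, hard filter, optional model filter."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .filters import (FilterConfig, ModelFilter, apply_model_filter,
                      detect_indel_positions, hard_filter,
                      high_coverage_regions, train_model_filter)
from .genotyper import CoverageSummary, GenotyperConfig, call_variants

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    calls: list                    # every call, flags populated
    coverage: CoverageSummary
    model: ModelFilter | None = None

    @property
    def passing(self) -> list:
        return [c for c in self.calls if c.passing]


def genotype_and_filter(
    reads,
    reference: dict,
    genotyper_config: GenotyperConfig | None = None,
    filter_config: FilterConfig | None = None,
    known_sites: set | None = None,
    model_random_state: int = 0,
) -> PipelineResult:
    """Run calling plus both filter stages over one read set.

    The model filter is trained (and applied) only when a known-sites set
    is supplied; hard-filter rules always run. Indel positions and
    high-coverage intervals are derived from the read set itself.
    """
    gcfg = genotyper_config or GenotyperConfig()
    fcfg = filter_config or FilterConfig()
    calls, coverage = call_variants(reads, reference, gcfg)
    indels = detect_indel_positions(coverage.gap_events)
    high_cov = high_coverage_regions(coverage.usable_depth,
                                     fcfg.high_cov_quantile)
    hard_filter(calls, fcfg, indels, high_cov)
    model = None
    if known_sites is not None:
        model = train_model_filter(calls, known_sites, fcfg,
                                   random_state=model_random_state)
        apply_model_filter(calls, model)
    n_pass = sum(c.passing for c in calls)
    log.info("pipeline: %d calls, %d pass all filters", len(calls), n_pass)
    return PipelineResult(calls, coverage, model)
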