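"""Bundled benchmark confusion counts for MTI-style MeSH indexing.

Published micro-average counts (gold positives, true positives, false
positives, pooled over 1413 gold-indexed open-access articles and 18185
gold heading assignments) for MTI run over different document
representations: the full text, the MEDLINE citation (title + abstract),
and automatic summaries from the graph-based (``gr``) and concept-frequency
(``cf``) summarizers at 15/30/50% compression.  Only the raw counts are
stored; precision, recall and F1 are always recomputed from them with
:func:`summash.evaluation.micro_metrics`.
"""

from .evaluation import ConfusionCounts

#: representation -> (positives, tp, fp)
MTI_BENCHMARK_COUNTS: dict[str, ConfusionCounts] = {
    "fulltext": ConfusionCounts(positives=18185, tp=12089, fp=20125),
    "medline": ConfusionCounts(positives=18185, tp=11117, fp=7531),
    "gr_sum_15": ConfusionCounts(positives=18185, tp=11323, fp=9982),
    "gr_sum_30": ConfusionCounts(positives=18185, tp=11747, fp=12585),
    "gr_sum_50": ConfusionCounts(positives=18185, tp=11971, fp=15304),
    "cf_sum_15": ConfusionCounts(positives=18185, tp=11955, fp=15311),
    "cf_sum_30": ConfusionCounts(positives=18185, tp=11971, fp=15355),
    "cf_sum_50": ConfusionCounts(positives=18185, tp=11999, fp=16050),
}
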