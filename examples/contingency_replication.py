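"""Replication analysis for a 2x2 contingency design.

Participants endowed with a category (flowers or birds) judged which
category had fewer occurrences.  Each row of the table is a fixed-size
condition (independent multinomial sampling with row totals fixed); the
default Bayes factor tests independence between the endowed category and
the judgment, with symmetric Dirichlet(1) priors on the cell probabilities.
"""

from repbf import (
    CrossTable,
    DirichletPrior,
    bf10_contingency,
    pearson_chi_square,
    pool_tables,
    replication_bf,
)

labels = dict(row_labels=("Flowers", "Birds"),
              col_labels=("Fewer flowers", "Fewer birds"))
original = CrossTable(((15, 12), (8, 21)), **labels)
replication = CrossTable(((11, 16), (14, 10)), **labels)
pooled = pool_tables(original, replication)

prior = DirichletPrior(1.0)
orig = bf10_contingency(original, prior)
complete = bf10_contingency(pooled, prior)
rep_bf = replication_bf(complete.bf10, orig.bf10)

stat, dof = pearson_chi_square(original)
print(f"original table: chi2({dof}, N={original.total}) = {stat:.2f}, "
      f"BF10 = {orig.bf10:.3f}")
print(f"pooled table {pooled.counts}: BF10 = {complete.bf10:.3f}")
print(f"replication BF10(d_rep | d_orig) = {rep_bf:.3f}")
print(f"null predicted the replication data {1 / rep_bf:.2f}x better")

# What the numbers mean: the original association was modest (BF10 = 2.880,
# chi-square significant at 4.52); pooling with the replication reverses the
# direction of evidence (0.298), and the replication data alone — given the
# original — favor independence by a factor of about 9.7.
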