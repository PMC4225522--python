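"""From event weights to a co-evolution score and its p-value.

Two gene families left candidate duplication events on the same species
branch: family 1 with support weights {1, 0.5, 0.5} (fractions of
most-parsimonious reconciliations containing each event), family 2 with
{0.6, 0.2}.  The script builds the Poisson-binomial distributions of the
actual event counts, the expected number of events in common, and the
exact p-value of that score under random event placement.
"""

import dtlcoev as dc

S = dc.parse_dated_newick("((A:1,B:1):1,C:2);")
branch = S.label_to_leaf["A"]

W1 = dc.WeightedEventSet(S)
for w in (1.0, 0.5, 0.5):
    W1.add(branch, "D", w)
W2 = dc.WeightedEventSet(S)
for w in (0.6, 0.2):
    W2.add(branch, "D", w)

dX = dc.count_distribution(W1.weights(branch, "D"))
dY = dc.count_distribution(W2.weights(branch, "D"))
print("P(X3 = 0..3) =", dX.round(4).tolist())
print("P(Y2 = 0..2) =", dY.round(4).tolist())
print("expected events in common on this branch:",
      round(dc.expected_common(dX, dY), 4))

res = dc.detect(S, event_sets=(W1, W2))
print(f"score X = {res.score:.2f}, N1 = {res.n1}, N2 = {res.n2}, "
      f"N = {res.n_bins} bins")
print(f"p-value = {res.p_value:.4f} -> "
      f"{'co-evolution' if res.significant else 'no co-evolution'} at 0.05")
# The score 0.77 says the two families are expected to share 0.77
# duplication events on this branch; the p-value is the chance that two
# independent families with 2 and 1 events scattered over the 12
# (branch, type) bins would overlap this much.
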