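"""Align two views of one synthetic manifold and score the result.

Builds a Swiss-roll sample rendered as two high-dimensional feature
matrices, computes geodesic dissimilarities, runs the two-domain joint MDS
and reports FOSCTTM (0 = every sample lands next to its true counterpart,
0.5 = random) plus k-NN label transfer accuracy.
"""

from jointmds import (
    foscttm,
    geodesic_distances,
    joint_mds,
    label_transfer_accuracy,
    make_triplet,
    normalize_dissimilarity,
    pairwise_euclidean,
)

F1, F2, _, labels = make_triplet("swiss_roll", seed=0, n=150, dims=(300, 500, 100))

D1 = normalize_dissimilarity(geodesic_distances(pairwise_euclidean(F1), k=10))
D2 = normalize_dissimilarity(geodesic_distances(pairwise_euclidean(F2), k=10))

res = joint_mds(D1, D2, d=2, lam=1.0, eps=0.001, seed=0)

f = foscttm(res.Z, res.Z_prime)
acc = label_transfer_accuracy(res.Z, labels, res.Z_prime, labels, k=5)
print(f"converged: {res.converged} after {res.n_iter} outer iterations")
print(f"FOSCTTM: {f:.4f}   (fraction of wrong samples closer than the true match)")
print(f"label transfer accuracy (k=5): {acc:.3f}")
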