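# bucketlcs

Pairwise comparison of genetic maps modelled as **bucket orders**, via
efficient longest-common-subsequence algorithms.

## The problem

A genetic map orders markers (SNPs, microsatellites, genes) along a
chromosome, but markers in complete linkage disequilibrium — or mapped
to the exact same position — cannot be ordered relative to one another.
A map is therefore not a permutation but a *bucket order*: a totally
ordered sequence of disjoint buckets B₁, …, Bₜ, with x ≺ y exactly when
x's bucket precedes y's, and x ≁ y (incomparable) exactly when they
share a bucket. Breeders and assemblers routinely hold several
alternative maps of the same chromosome (different populations,
different ordering software) and need to quantify and visualize their
agreement.

The largest set of collinear markers between two maps π₁, π₂ is their
**LCS**: the longest sequence that is a subsequence of some linear
extension of each. A stricter variant, the **LCIS** (longest common
*induced* subsequence), additionally refuses to order any two markers
that *neither* map orders, so it never invents order that no input
supports.

## The method

1. **Homogenization** refines both orders onto their shared markers
   D = D₁ ∩ D₂ so that two markers share a bucket in a refined order
   iff they do in *both* inputs. The two refined orders then carry
   identical buckets (in possibly different sequence), and the sets of
   common (induced) subsequences are provably unchanged. Implemented
   both by per-bucket comparison sorting, O(n log n), and by an
   integer-relabeling counting sort, O(n).
2. Numbering the n_b refined buckets by their position in refined
   order 1 turns refined order 2 into a permutation of 1..n_b. Then
   - **LCIS** = longest increasing subsequence (LIS) of that
     permutation (one marker per bucket), and
   - **LCS** = heaviest increasing subsequence (HIS) with bucket sizes
     as weights (a matched bucket contributes all its markers),
   both solved in O(n log n) with a Fenwick max tree (`lcs_fast`).
3. A quadratic dynamic program over the bucket sequences (`lcs`) covers
   the same ground in O(n log n + n_b²) and additionally supports
   **counting** and **enumerating** all optimal solutions.

The key win over running a plain LCS on marker sequences is that the
quadratic part scales with the number of homogenized *buckets*, not
markers — decisive for dense maps where hundreds of markers share a
position.

## Worked example

```python
from bucketlcs import BucketOrder, homogenize_pair, lcs, lcs_fast, enumerate_optimal

pi1 = BucketOrder([{"k"}, {"a","b"}, {"l","c"}, {"d","e","f"}, {"i","j"}, {"g","h"}])
pi2 = BucketOrder([{"g","h"}, {"c","d","e","f"}, {"m","q"}, {"r","a"}, {"b","n"}, {"o","p","l"}])

pair = homogenize_pair(pi1, pi2)
print(pair.order1h)   # BucketOrder({a}, {b}, {c}, {l}, {d,e,f}, {g,h})
print(pair.order2h)   # BucketOrder({g,h}, {c}, {d,e,f}, {a}, {b}, {l})

print(lcs(pi1, pi2))              # CommonSubsequence(elements=('c', 'd', 'e', 'f'), mode='lcs')
print(lcs_fast(pi1, pi2, True))   # CommonSubsequence(elements=('a', 'b', 'l'), mode='lcis')
print(len(enumerate_optimal(pi1, pi2, limit=10)))   # 6
```

The maps agree on the run c→(d,e,f): LCS length 4, and since d, e, f
are unordered in both maps there are 6 distinct optimal sequences. The
stricter LCIS keeps a, b, l (length 3): the only three shared markers
whose relative order is supported by at least one map at every step.

The same operations are available from the shell:

```sh
bucketlcs simulate --n 1000 --seed 7 --out1 m1.txt --out2 m2.txt
bucketlcs compare --map1 m1.txt --map2 m2.txt --format buckets --out-report report.json
bucketlcs homogenize --map1 map_DL.tsv --map2 map_DS.tsv --chromosome 3A
```

`compare` prints the LC(I)S and its length, and can emit a JSON
congruence report (lengths, shared-marker counts, collinearity ratios)
plus a per-marker TSV classification (`in_lcs` / `conflicting` /
`only_map1` / `only_map2`) for dual-synteny coloring.

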