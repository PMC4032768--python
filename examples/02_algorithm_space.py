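"""Enumerate the component-based algorithm design space.

Every representative-based clustering algorithm here is one choice per
subproblem: 7 initializations x 4 distances x 3 updates x 6 evaluation
measures = 504 algorithms, and crossing with the 4 per-feature normalization
methods gives 2016 experiment configurations.
"""

from metaclust import enumerate_algorithm_space, parse_spec

specs = enumerate_algorithm_space()
print(f"algorithms in the RC cross-product: {len(specs)}")
print(f"with the 4 normalizations:         {len(enumerate_algorithm_space(True))}")

print("\nfirst five algorithms (lexicographic):")
for spec in specs[:5]:
    print(f"  {spec.name}")

kmeans = parse_spec("RANDOM-EUCLIDEAN-MEAN-COMPACT")
print(f"\nplain k-means reconstructed:  {kmeans.name}")
print(f"  init={kmeans.init}  distance={kmeans.distance}  "
      f"update={kmeans.update}  evaluate={kmeans.evaluate}")
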