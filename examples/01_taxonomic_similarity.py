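"""Wu-Palmer similarity over a small hand-written concept taxonomy.

Builds an ontology fragment (entity -> living thing / artifact -> ...),
computes pairwise taxonomic similarity over eight basic-level categories
and prints the matrix. Values are 2N / (N1 + N2): N1, N2 are the node
depths of the two concepts from the root, N the depth of their lowest
common subsumer, so similarity rises with shared ancestry and reaches 1
only for a concept with itself.
"""

from taxorsa import parse_taxonomy, taxonomy_similarity_matrix

EDGES = """\
child\tparent
living_thing\tentity
artifact\tentity
bird\tliving_thing
mammal\tliving_thing
device\tartifact
conveyance\tartifact
crane\tbird
flamingo\tbird
poodle\tmammal
tabby\tmammal
laptop\tdevice
lamp\tdevice
canoe\tconveyance
tricycle\tconveyance
"""

LEAVES = ["crane", "flamingo", "poodle", "tabby",
          "laptop", "lamp", "canoe", "tricycle"]


def main() -> None:
    tree = parse_taxonomy(EDGES, "edge_list", LEAVES)
    matrix = taxonomy_similarity_matrix(tree)
    print(matrix.to_dataframe().round(3).to_string())
    crane_flamingo = tree.wu_palmer_similarity("crane", "flamingo")
    crane_laptop = tree.wu_palmer_similarity("crane", "laptop")
    print(f"\ncrane vs flamingo (same bird family): {crane_flamingo:.3f}")
    print(f"crane vs laptop (share only the root): {crane_laptop:.3f}")
    print("Categories under one superordinate score 0.75; across the "
          "living-thing/artifact split only 0.25.")


if __name__ == "__main__":
    main()
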