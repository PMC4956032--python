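"""Build the packaged synthetic stand-in topology with Grafen lengths."""
from spinetrait.treeio import read_tree, write_tree

paraves = [
    ["Buitreraptor", "Rahonavis",
     ["Microraptor", ["Bambiraptor", ["Deinonychus",
      ["Achillobator", ["Velociraptor", "Saurornitholestes"]]]]]],
    ["Sinovenator", "Mei", "Jinfengopteryx", ["Troodon", "Saurornithoides"]],
    "Archaeopteryx",
]
oviraptorosaurs = ["Avimimus", "Caudipteryx", "Microvenator",
                   ["Chirostenotes", ["Citipati", "Khaan"]]]
maniraptora = [["Mononykus", "Shuvuuia"],
               ["Falcarius", [oviraptorosaurs, paraves]]]
ornithomimosaurs = ["Shenzhousaurus",
                    ["Archaeornithomimus", "Garudimimus",
                     ["Ornithomimus", "Struthiomimus"]]]
tyrannosauroids = ["Guanlong", ["Albertosaurus", ["Daspletosaurus", "Tyrannosaurus"]]]
coelurosaurs = [
    ["Compsognathus", "Huaxiagnathus", "Sinosauropteryx", "Mirischia"],
    ["Coelurus", "Ornitholestes",
     [tyrannosauroids, [ornithomimosaurs, maniraptora]]],
]
allosauroids = ["Allosaurus", ["Acrocanthosaurus", "Neovenator", "Tyrannotitan"],
                "Fukuiraptor"]
spinosauroids = ["Torvosaurus", ["Baryonyx", "Spinosaurus"]]
ceratosaurs = ["Ceratosaurus", ["Carnotaurus", "Majungasaurus", "Masiakasaurus"]]
neotheropods = [["Coelophysis", "Liliensternus"],
                ["Dilophosaurus",
                 [ceratosaurs, [spinosauroids, [allosauroids, coelurosaurs]]]]]
root = [["Herrerasaurus", "Staurikosaurus"], "Eoraptor", neotheropods]


def newick(node):
    if isinstance(node, str):
        return node
    return "(" + ",".join(newick(c) for c in node) + ")"


def tips(node):
    if isinstance(node, str):
        return [node]
    return [t for c in node for t in tips(c)]


names = tips(root)
assert len(names) == len(set(names)) == 56, len(names)
tree = read_tree(newick(root) + ";", "newick", grafen=True)
print("tips:", tree.n_tips)
out = write_tree(tree)
with open("/root/pkg/src/spinetrait/data/standin_tree_synthetic.nwk", "w") as fh:
    fh.write(out)
print(out[:160])
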