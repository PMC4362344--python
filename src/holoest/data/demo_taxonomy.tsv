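# node	parent	rank
root	root	no rank
Bacteria	root	superkingdom
Proteobacteria	Bacteria	phylum
Alphaproteobacteria	Proteobacteria	class
Betaproteobacteria	Proteobacteria	class
Gammaproteobacteria	Proteobacteria	class
Deltaproteobacteria	Proteobacteria	class
Bacteroidetes	Bacteria	phylum
Planctomycetes	Bacteria	phylum
Cyanobacteria	Bacteria	phylum
Firmicutes	Bacteria	phylum
Actinobacteria	Bacteria	phylum
Eukaryota	root	superkingdom
Rhizaria	Eukaryota	supergroup
Acantharea	Rhizaria	class
Polycystinea	Rhizaria	class
Cercozoa	Rhizaria	phylum
Foraminifera	Rhizaria	phylum
Sticholonchida	Rhizaria	order
Alveolata	Eukaryota	supergroup
Dinophyceae	Alveolata	class
Apicomplexa	Alveolata	phylum
Ciliophora	Alveolata	phylum
Perkinsea	Alveolata	class
Stramenopiles	Eukaryota	supergroup
Bacillariophyta	Stramenopiles	phylum
Pelagophyceae	Stramenopiles	class
Oomycetes	Stramenopiles	class
Haptophyta	Eukaryota	phylum
Cryptophyta	Eukaryota	phylum
Opisthokonta	Eukaryota	supergroup
Metazoa	Opisthokonta	kingdom
Fungi	Opisthokonta	kingdom
Choanoflagellata	Opisthokonta	class
Amoebozoa	Eukaryota	supergroup
Archaeplastida	Eukaryota	supergroup
Chlorophyta	Archaeplastida	phylum
Streptophyta	Archaeplastida	phylum
Rhodophyta	Archaeplastida	phylum
Excavata	Eukaryota	supergroup
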