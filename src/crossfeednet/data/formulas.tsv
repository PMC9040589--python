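name	formula	class
succinate	C4H6O4	carboxylic acid
malate	C4H6O5	carboxylic acid
fumarate	C4H4O4	carboxylic acid
citrate	C6H8O7	carboxylic acid
pyruvate	C3H4O3	carboxylic acid
2-oxobutanoate	C4H6O3	carboxylic acid
lactate	C3H6O3	carboxylic acid
acetate	C2H4O2	short-chain fatty acid
propionate	C3H6O2	short-chain fatty acid
butyrate	C4H8O2	short-chain fatty acid
arginine	C6H14N4O2	amino acid
histidine	C6H9N3O2	amino acid
lysine	C6H14N2O2	amino acid
cysteine	C3H7NO2S	amino acid
serine	C3H7NO3	amino acid
alanine	C3H7NO2	amino acid
glycine	C2H5NO2	amino acid
aspartate	C4H7NO4	amino acid
glutamate	C5H9NO4	amino acid
leucine	C6H13NO2	amino acid
isoleucine	C6H13NO2	amino acid
valine	C5H11NO2	amino acid
threonine	C4H9NO3	amino acid
methionine	C5H11NO2S	amino acid
phenylalanine	C9H11NO2	amino acid
tyrosine	C9H11NO3	amino acid
tryptophan	C11H12N2O2	amino acid
ornithine	C5H12N2O2	amino acid derivative
4-aminobutanoate	C4H9NO2	amino acid derivative
3-methyl-2-oxobutanoate	C5H8O3	carboxylic acid
xanthine	C5H4N4O2	nucleobase
hypoxanthine	C5H4N4O	nucleobase
adenine	C5H5N5	nucleobase
guanine	C5H5N5O	nucleobase
uracil	C4H4N2O2	nucleobase
thymine	C5H6N2O2	nucleobase
glucose	C6H12O6	carbohydrate
fructose	C6H12O6	carbohydrate
ribose	C5H10O5	carbohydrate
sorbitol	C6H14O6	carbohydrate
ascorbate	C6H8O6	vitamin
nicotinate	C6H5NO2	vitamin
pantothenate	C9H17NO5	vitamin
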