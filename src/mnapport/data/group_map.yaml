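# Default food item -> food group mapping (editable; nine groups, with
# nuts present for Kenya only in the default item lists).
maize: maize
rice: grain
beans: pulses
pigeon_peas: pulses
sukuma_wiki: leafy_veg
pumpkin_leaves: leafy_veg
spinach: leafy_veg
tomato: vegetables
onion: vegetables
cassava: root_tuber
sweet_potato: root_tuber
banana: fruit
mango: fruit
sunflower_seeds: seeds
groundnut: nuts
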