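>ctldref01 synthetic reference c-type lectin domain (coral-like), EPN glucose/mannose type
CYIKGYLIHNWLGVYHACIFDQRAKGMVYRQVTVQDLEGIQEPNENHTVRAHITTPCMFGHSSFDC
>ctldref02 synthetic reference c-type lectin domain (coral-like), EPN glucose/mannose type
CYPWLGVLRRPCVDRATKVAFNTNDDKNNRGYTRHIEPNHMNPMTDMQIFCNFEDKQNMFILAC
>ctldref03 synthetic reference c-type lectin domain (anemone-like), EPN glucose/mannose type
CTEWVGIARYMCKQAVPKEEPNHIPHQYGKMNNKVEYMDLNMDEANHICRYDKYSEPPQLGYTHC
>ctldref04 synthetic reference c-type lectin domain (nematode-like), LND galactose type
CHKNWVGVSMYNEKVVCMYFADHMTRELRMLNDHQYGFPVLGGNELIINTEVTANCYLDKQNFKGPC
>ctldref05 synthetic reference c-type lectin domain (choanoflagellate-like), LND galactose type
CRNYIWVGLNDAAVCRQHMPEFADKGQAQPHEIHTRLLQFAFEPLNDHRIIHKYCIDKVVGPTFQYYC
>ctldref06 synthetic reference c-type lectin domain (apicomplexan-like), EPN glucose/mannose type
CSYSWVGLDQLSHKANDCGFMQMLYLEPNIHLLVLFEEEAPNTYRNHKEGQEREQNGTDDACRYKLIQKYAQKC
>ctldref07 synthetic reference c-type lectin domain (cryptophyte-like), LND galactose type
CPADAMHRLFIWLGVMNMRRCLSFILLAASEYPLNDYAKMTELDIFPAEVIFKFGMAHQCYMAPGYFQIC
>ctldref08 synthetic reference c-type lectin domain (pelagophyte-like), EPN glucose/mannose type
CQRPRVEHWLGLLVQCIPKMDENFFTIQRLEPNDPMIYHMTPHGPRKAQVAKSQGVCDSQRAQNDEC
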