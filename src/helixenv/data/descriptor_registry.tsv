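name	category
Temperature_Factor_CA	Structural
Dihedral_Angle_PHI	Structural
Dihedral_Angle_PSI	Structural
Dihedral_Chi1	Structural
Dihedral_Chi2	Structural
Dihedral_Chi3	Structural
Dihedral_Chi4	Structural
Density_IFR	Structural
Density_Internal	Structural
Space_Clash_Number	Structural
Space_Clash_Percent	Structural
Cross_Link_Order_CA	Geometric
Cross_Pres_Order_CA	Geometric
HBMM	Contacts
HBMWM	Contacts
HBMWWM	Contacts
HBMS	Contacts
HBMWS	Contacts
HBMWWS	Contacts
HBSS	Contacts
HBSWS	Contacts
HBSWWS	Contacts
Hydrophobic	Contacts
Aromatic	Contacts
Ch_attractive	Contacts
Ch_repulsive	Contacts
Disulfide	Contacts
Number_Unused_Contact	Unused Contacts
Electrostatic_Potential_at_CA	Physical Chemical
Electrostatic_Potential_Average	Physical Chemical
Electrostatic_Potential_at_LHA	Physical Chemical
HBMM_WNADist	WNA
HBMWM_WNADist	WNA
HBMWWM_WNADist	WNA
HBMS_WNADist	WNA
HBMWS_WNADist	WNA
HBMWWS_WNADist	WNA
HBSS_WNADist	WNA
HBSWS_WNADist	WNA
HBSWWS_WNADist	WNA
Hydrophobic_WNADist	WNA
Aromatic_WNADist	WNA
Ch_attractive_WNADist	WNA
Ch_repulsive_WNADist	WNA
Disulfide_WNADist	WNA
Number_Unused_Contact_WNADist	WNA
Electrostatic_Potential_at_CA_WNADist	WNA
Electrostatic_Potential_Average_WNADist	WNA
Electrostatic_Potential_at_LHA_WNADist	WNA
HBMM_WNASurf	WNA
HBMWM_WNASurf	WNA
HBMWWM_WNASurf	WNA
HBMS_WNASurf	WNA
HBMWS_WNASurf	WNA
HBMWWS_WNASurf	WNA
HBSS_WNASurf	WNA
HBSWS_WNASurf	WNA
HBSWWS_WNASurf	WNA
Hydrophobic_WNASurf	WNA
Aromatic_WNASurf	WNA
Ch_attractive_WNASurf	WNA
Ch_repulsive_WNASurf	WNA
Disulfide_WNASurf	WNA
Number_Unused_Contact_WNASurf	WNA
Electrostatic_Potential_at_CA_WNASurf	WNA
Electrostatic_Potential_Average_WNASurf	WNA
Electrostatic_Potential_at_LHA_WNASurf	WNA
Accessible_in_Isolation	Others
Hydrophobicity_KDI	Others
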