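common_name,scientific_name,population_tag,current_category,breeding,wintering,migration,synchronicity,distance,specialization,external_score,published_sum,published_revised
Black-necked Stilt,Himantopus mexicanus,,2,+2,+1,+1,0,0,+2,0,6,3
American Avocet,Recurvirostra americana,,3,+2,+2,+2,0,0,+1,1,7,4
American Oystercatcher,Haematopus palliatus,,4,+2,+2,+2,0,0,+2,4,8,6
Black Oystercatcher,Haematopus bachmani,,4,+1,+1,+1,0,0,+2,4,5,5
Black-bellied Plover,Pluvialis squatarola,,3,+2,+1,+1,+1,+1,+2,3,8,5
American Golden-Plover,Pluvialis dominica,,4,+2,+1,+1,+1,+2,+1,2,8,6
Pacific Golden-Plover,Pluvialis fulva,,4,+2,0,0,+1,0,+2,3,5,5
Snowy Plover,Charadrius nivosus,coastal,5,+2,+2,+2,0,0,+2,2,8,6
Snowy Plover,,inland,5,+1,+1,+2,0,0,+2,2,6,6
Wilson's Plover,Charadrius wilsonia,,4,+2,+2,+2,0,0,+2,3,8,6
Semipalmated Plover,Charadrius semipalmatus,,2,+1,+1,+1,+1,+1,+2,1,7,3
Piping Plover,Charadrius melodus,coastal,5,+2,+2,+2,0,0,+2,3,8,6
Piping Plover,,inland,5,+2,+2,+1,0,0,+2,3,7,6
Killdeer,Charadrius vociferous,,3,0,0,0,0,0,0,0,0,3
Mountain Plover,Charadrius montanus,,5,-1,+1,+1,0,0,+2,1,3,5
Spotted Sandpiper,Actitis macularius,,2,0,0,0,0,+1,0,1,1,2
Solitary Sandpiper,Tringa solitaria,,4,-1,+2,+2,+1,+1,+2,2,7,5
Wandering Tattler,Tringa incana,,3,0,+1,0,+1,+1,+1,4,4,4
Greater Yellowlegs,Tringa melanoleuca,,3,0,0,0,+1,+1,+2,1,4,4
Willet,Tringa semipalmata,eastern,3,+2,+2,+2,0,0,+1,2,7,4
Willet,,western,3,+1,+1,+2,0,0,+1,2,5,4
Lesser Yellowlegs,Tringa flavipes,,3,-1,+1,+1,+1,+1,+1,1,4,4
Upland Sandpiper,Bartramia longicauda,,4,0,0,0,0,+1,+2,2,3,4
Whimbrel,Numenius phaeopus,,4,+2,+2,+2,+1,+1,+1,3,9,6
Bristle-thighed Curlew,Numenius tahitiensis,,4,-1,+2,+1,+1,+2,+1,4,6,5
Long-billed Curlew,Numenius americanus,,5,+2,+1,0,0,0,+2,2,5,6
Hudsonian Godwit,Limosa haemastica,,4,0,+1,0,+1,+2,0,4,4,5
Bar-tailed Godwit,Limosa lapponica,,4,+2,+2,+2,+1,+2,+2,4,11,6
Marbled Godwit,Limosa fedoa,,4,+1,+1,+1,0,0,+2,1,5,5
Ruddy Turnstone,Arenaria interpres,,4,+1,+2,+2,+2,+1,+2,3,10,6
Black Turnstone,Arenaria melanocephala,,4,+1,+1,+1,+1,0,+2,4,6,5
Red Knot,Calidris canutus,,4,+1,+2,+2,+2,+1,+2,4,10,6
Surfbird,Calidris virgata,,4,+1,+2,+2,+1,+1,+2,5,9,6
Stilt Sandpiper,Calidris himantopus,,3,+2,0,0,+1,+1,+2,3,6,4
Sanderling,Calidris alba,,4,+2,+2,+2,+2,+1,+2,3,11,6
Dunlin,Calidris alpina,,3,+2,+2,+1,+1,0,+2,3,8,5
Rock Sandpiper,Calidris ptilocnemis,,3,+1,0,0,+1,0,+2,4,4,4
Purple Sandpiper,Calidris maritima,,2,+1,0,0,0,0,+2,4,3,2
Baird's Sandpiper,Calidris bairdii,,2,0,0,0,+1,+2,+2,3,5,3
Least Sandpiper,Calidris minutilla,,3,0,+1,+1,+1,+1,+1,3,5,4
White-rumped Sandpiper,Calidris fuscicollis,,2,+2,-1,+1,+1,+2,+1,3,6,3
Buff-breasted Sandpiper,Calidris subruficollis,,4,+2,0,0,+1,+2,+2,3,7,5
Pectoral Sandpiper,Calidris melanotos,,2,+2,0,0,+1,+1,+2,3,6,3
Semipalmated Sandpiper,Calidris pusilla,,3,+2,+2,+1,+2,+1,+2,4,10,5
Western Sandpiper,Calidris mauri,,4,+1,+2,+1,+1,+1,+1,4,7,5
Short-billed Dowitcher,Limnodromus griseus,,4,0,+2,+2,+1,+1,+1,4,7,5
Long-billed Dowitcher,Limnodromus scolopaceus,,4,+2,+1,+1,+1,+1,+1,3,7,5
Wilson's Snipe,Gallinago delicata,,3,0,0,0,0,+1,+1,0,2,3
American Woodcock,Scolopax minor,,4,+1,-1,-1,0,0,+2,1,1,4
Wilson's Phalarope,Phalaropus tricolor,,4,+1,+1,+1,0,+1,0,3,4,5
Red-necked Phalarope,Phalaropus lobatus,,3,+2,0,0,+1,+1,+2,1,6,4
Red Phalarope,Phalaropus fulicarius,,3,+2,0,0,+1,+1,+2,3,6,4
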